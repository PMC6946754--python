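"""Elemental formulas, monoisotopic cation masses and sum-formula annotation.

PTR-MS detects protonated (or otherwise singly charged) cations, so every
mass here is a *cation* mass-to-charge ratio in Thomson (Th): the sum of
monoisotopic atomic masses minus one electron mass per unit of positive
charge.  At a mass accuracy of ~1 mTh the electron mass (0.55 mTh) is not
negligible and is always subtracted.

Formulas are written in Hill notation with a trailing charge sign, e.g.
``"C5H9O+"`` for protonated isoprene's oxygen analogue (2-methylbutanal).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

__all__ = [
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "IonFormula",
    "FormulaCandidate",
    "parse_formula",
    "monoisotopic_mz",
    "annotate",
    "rdbe",
]

#: Monoisotopic atomic masses in unified atomic mass units (CODATA/AME).
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "O": 15.9949146221,
    "N": 14.0030740052,
    # convenience entries for calibrant chemistry
    "O18": 17.9991604,
    "S": 31.97207069,
}

#: Electron mass in u; subtracted once per positive charge.
ELECTRON_MASS: float = 0.000548579909

# isotope tokens (O18) must win over the bare element symbol
_TOKEN_RE = re.compile(r"(O18|[A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class IonFormula:
    """An elemental composition with an integer charge.

    ``element_counts`` maps element symbols to non-negative counts; at least
    one atom must be present.  ``charge`` defaults to +1, the only charge
    state produced by proton-transfer ionization from H3O+.
    """

    element_counts: tuple[tuple[str, int], ...]
    charge: int = 1

    def __post_init__(self) -> None:
        counts = dict(self.element_counts)
        if not counts or all(v == 0 for v in counts.values()):
            raise ValueError("formula must contain at least one atom")
        for el, n in counts.items():
            if el not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element symbol: {el!r}")
            if n < 0:
                raise ValueError(f"negative count for element {el}")

    @classmethod
    def from_counts(cls, counts: dict[str, int], charge: int = 1) -> "IonFormula":
        items = tuple(sorted((e, n) for e, n in counts.items() if n > 0))
        return cls(items, charge)

    @property
    def counts(self) -> dict[str, int]:
        return dict(self.element_counts)

    def hill(self) -> str:
        """Hill notation: C first, H second, remaining elements alphabetical."""
        c = self.counts
        parts: list[str] = []
        for el in ["C", "H"] + sorted(k for k in c if k not in ("C", "H")):
            n = c.get(el, 0)
            if n == 0:
                continue
            parts.append(el + (str(n) if n > 1 else ""))
        sign = "+" if self.charge > 0 else "-"
        return "".join(parts) + sign * abs(self.charge)

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return self.hill()


def parse_formula(text: str) -> IonFormula:
    """Parse Hill-notation formula text such as ``"C5H9O+"`` or ``"H3O+"``.

    Trailing sign characters set the charge (``"+"`` → +1, ``"++"`` → +2,
    ``"-"`` → −1); absent a sign the charge defaults to +1, matching the
    proton-transfer convention used throughout.  The token ``O18`` denotes
    the heavy-oxygen isotope (as in the primary-ion isotopologue
    ``"H3O18+"``).
    """
    s = text.strip()
    charge = 1
    m = re.search(r"([+-]+)$", s)
    if m:
        signs = m.group(1)
        if len(set(signs)) > 1:
            raise ValueError(f"mixed charge signs in {text!r}")
        charge = len(signs) if signs[0] == "+" else -len(signs)
        s = s[: m.start()]
    if not s:
        raise ValueError(f"empty formula: {text!r}")
    counts: dict[str, int] = {}
    pos = 0
    for tok in _TOKEN_RE.finditer(s):
        if tok.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at {s[pos:]!r}")
        el, num = tok.group(1), tok.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element symbol: {el!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = tok.end()
    if pos != len(s):
        raise ValueError(f"cannot parse formula {text!r} at {s[pos:]!r}")
    return IonFormula.from_counts(counts, charge)


def _as_formula(formula: "IonFormula | str") -> IonFormula:
    return parse_formula(formula) if isinstance(formula, str) else formula


def neutral_mass(formula: "IonFormula | str") -> float:
    """Sum of monoisotopic atomic masses in u, ignoring charge."""
    f = _as_formula(formula)
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in f.element_counts)


def monoisotopic_mz(formula: "IonFormula | str") -> float:
    """Theoretical m/z of an ion in Th.

    Computed as (sum of monoisotopic atomic masses − z·m_e) / |z| for
    positive ions (electrons added for negative ions).  Raises on zero
    charge, for which m/z is undefined.
    """
    f = _as_formula(formula)
    if f.charge == 0:
        raise ValueError("m/z undefined for zero charge")
    return (neutral_mass(f) - f.charge * ELECTRON_MASS) / abs(f.charge)


def rdbe(formula: "IonFormula | str") -> float:
    """Ring-and-double-bond equivalents of the neutral composition.

    RDBE = C − H/2 + N/2 + 1 (O contributes zero).  For protonated even-
    electron cations the value is half-integral; callers filtering on
    RDBE ≥ 0 should evaluate it on the ion composition as given.
    """
    c = _as_formula(formula).counts
    return c.get("C", 0) - c.get("H", 0) / 2 + c.get("N", 0) / 2 + 1


@dataclass(frozen=True)
class FormulaCandidate:
    """One sum-formula assignment for an observed peak."""

    formula: IonFormula
    theoretical_mz: float
    delta_mz: float  # observed − theoretical, Th

    def __str__(self) -> str:  # pragma: no cover
        return f"{self.formula.hill()} ({self.theoretical_mz:.4f} Th, Δ={self.delta_mz:+.4f})"


def _n_heteroatoms(f: IonFormula) -> int:
    return sum(n for el, n in f.element_counts if el not in ("C", "H"))


def annotate(
    observed_mz: float,
    tolerance: float,
    element_bounds: dict[str, int] | None = None,
    charge: int = 1,
    min_rdbe: float | None = None,
) -> list[FormulaCandidate]:
    """Exhaustively enumerate sum formulas within ``tolerance`` Th of a peak.

    Every composition on the bounded lattice (default C ≤ 20, H ≤ 40,
    O ≤ 5, N ≤ 3) is tested; candidates are returned sorted by |Δm/z|
    ascending, with ties broken by fewer heteroatoms and then by Hill
    string, so the ordering is fully deterministic.  With ``min_rdbe``
    set, compositions below that ring-and-double-bond count are dropped.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if element_bounds is None:
        element_bounds = {"C": 20, "H": 40, "O": 5, "N": 3}
    for el in element_bounds:
        if el not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element symbol: {el!r}")
    elements = sorted(element_bounds)
    ranges = [range(element_bounds[el] + 1) for el in elements]
    out: list[FormulaCandidate] = []
    target = observed_mz * abs(charge) + charge * ELECTRON_MASS
    # prune: cheapest-first loop with early mass cutoff
    for combo in itertools.product(*ranges):
        if not any(combo):
            continue
        mass = sum(MONOISOTOPIC_MASS[el] * n for el, n in zip(elements, combo))
        if abs(mass - target) > tolerance * abs(charge):
            continue
        f = IonFormula.from_counts(dict(zip(elements, combo)), charge)
        if min_rdbe is not None and rdbe(f) < min_rdbe:
            continue
        th = monoisotopic_mz(f)
        out.append(FormulaCandidate(f, th, observed_mz - th))
    out.sort(key=lambda c: (abs(c.delta_mz), _n_heteroatoms(c.formula), c.formula.hill()))
    return out
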