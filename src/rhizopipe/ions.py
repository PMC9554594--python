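"""Accurate-mass annotation of negative-mode ions and group comparison.

Flow-injection TOF instruments report centroided ion lists (m/z plus one
intensity per sample).  Each expected metabolite is observed as its
deprotonated molecular anion [M-H]-, whose m/z is the neutral monoisotopic
mass minus the mass of a proton (1.00727646 Da; the electron stays on the
anion).  An ion is annotated with a compound when |observed - expected| is
within a mass tolerance, 0.001 Da by default; if several compounds fall
inside the tolerance the smallest absolute error wins.

Group comparison of annotated ion counts (one-way ANOVA + Tukey letters)
delegates to :mod:`rhizopipe.groupstats`; raw counts are compared without
normalisation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .groupstats import GroupedMeasurements, compact_letters, one_way_anova, tukey_hsd

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "CompoundRef",
    "IonRecord",
    "Annotation",
    "parse_formula",
    "monoisotopic_mass",
    "deprotonated_mz",
    "annotate_ions",
    "compare_ion_groups",
]

#: Monoisotopic atomic masses (Da) of the supported elements, CODATA/IUPAC values.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
}

#: Mass of the proton (Da); removed on deprotonation, the electron is retained.
PROTON_MASS = 1.00727646

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a plain molecular formula (e.g. ``C10H9NO2``) into element counts."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValidationError(f"cannot parse formula {formula!r} at position {pos}")
        if not m.group(0):
            break
        elem, num = m.group(1), m.group(2)
        if elem not in MONOISOTOPIC_MASS:
            raise ValidationError(f"unsupported element {elem!r} in formula {formula!r}")
        counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
        pos = m.end()
    if pos != len(formula):
        raise ValidationError(f"cannot parse formula {formula!r} at position {pos}")
    return counts


def monoisotopic_mass(formula: str | dict[str, int]) -> float:
    """Neutral monoisotopic mass (Da) of a molecular formula; empty formula -> 0."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    mass = 0.0
    for elem, n in counts.items():
        if elem not in MONOISOTOPIC_MASS:
            raise ValidationError(f"unsupported element {elem!r}")
        if n < 0:
            raise ValidationError("element counts must be >= 0")
        mass += MONOISOTOPIC_MASS[elem] * n
    return mass


def deprotonated_mz(neutral_mass: float) -> float:
    """m/z of the [M-H]- anion: neutral mass minus the proton mass."""
    mz = neutral_mass - PROTON_MASS
    if mz <= 0:
        raise ValidationError("neutral mass must exceed the proton mass")
    return mz


@dataclass(frozen=True)
class CompoundRef:
    """A reference metabolite; the mass is always recomputed from the formula."""

    name: str
    formula: str

    @property
    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.formula)

    @property
    def mz_deprotonated(self) -> float:
        return deprotonated_mz(self.neutral_mass)


@dataclass(frozen=True)
class IonRecord:
    """One detected ion: m/z and per-sample intensities (ion counts)."""

    mz: float
    intensities: tuple[float, ...]
    samples: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.intensities) != len(self.samples):
            raise ValidationError("intensities and sample names must align")
        if any(v < 0 for v in self.intensities):
            raise ValidationError("ion counts must be >= 0")


@dataclass(frozen=True)
class Annotation:
    ion: IonRecord
    compound: CompoundRef
    delta_da: float  # observed - expected, signed


def annotate_ions(
    ions: list[IonRecord],
    compounds: list[CompoundRef],
    tolerance_da: float = 0.001,
) -> list[Annotation]:
    """Match ions to expected deprotonated molecules within a mass tolerance.

    One compound per ion: the smallest |delta| wins; deltas equal to within
    1e-5 Da break ties by compound name.  Unmatched ions simply yield no
    annotation.
    """
    if tolerance_da <= 0:
        raise ValidationError("tolerance_da must be > 0")
    expected = [(c.mz_deprotonated, c) for c in compounds]
    out: list[Annotation] = []
    for ion in ions:
        candidates = [
            (abs(ion.mz - mz), ion.mz - mz, c) for mz, c in expected if abs(ion.mz - mz) <= tolerance_da
        ]
        if not candidates:
            continue
        candidates.sort(key=lambda t: (round(t[0] / 1e-5), t[2].name))
        absd, delta, comp = candidates[0]
        out.append(Annotation(ion=ion, compound=comp, delta_da=delta))
    return out


def compare_ion_groups(
    annotation: Annotation,
    sample_groups: dict[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Group-wise ion counts for one annotated compound, with Tukey letters.

    Returns a table with one row per group: n, mean, min, max and the compact
    letter; groups sharing a letter are not significantly different at
    ``alpha`` (one-way ANOVA + Tukey HSD).
    """
    ion = annotation.ion
    missing = [s for s in ion.samples if s not in sample_groups]
    if missing:
        raise ValidationError(f"samples without a group assignment: {missing}")
    per_group: dict[str, list[float]] = {}
    for s, v in zip(ion.samples, ion.intensities):
        per_group.setdefault(sample_groups[s], []).append(v)
    data = GroupedMeasurements.from_dict(per_group)
    f_stat, p_val = one_way_anova(data)
    pmat = tukey_hsd(data, alpha=alpha)
    letters = compact_letters(pmat, list(data.groups), alpha=alpha, means=data.means())
    rows = []
    for g in data.groups:
        vals = np.asarray(per_group[g], dtype=float)
        rows.append(
            {
                "compound": annotation.compound.name,
                "group": g,
                "n": vals.size,
                "mean": float(vals.mean()),
                "min": float(vals.min()),
                "max": float(vals.max()),
                "letter": letters.as_dict()[g],
                "anova_F": f_stat,
                "anova_p": p_val,
            }
        )
    return pd.DataFrame(rows)
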