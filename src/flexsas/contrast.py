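"""Neutron scattering-length density, contrast and match-point calculations.

Implements sequence-based SLD/contrast arithmetic for (partially) deuterated
proteins in multi-component H2O/D2O buffers, in the style of the classic
contrast calculators used for contrast-variation SANS:

* protein SLD = sum of coherent scattering lengths over the atomic
  composition, divided by the composition-estimated molecular volume;
  non-exchangeable H are deuterated at the labelling fraction ``d``, and
  exchangeable H follow the solvent D2O fraction attenuated by the
  accessibility factor ``x`` (default 0.9);
* solvent SLD = number-density-weighted scattering-length sum over water and
  solutes, with solutes displacing water by their volume fraction; buffer
  components' chemical formulas are taken literally -- labile solute
  hydrogens exchange with the solvent only if a component declares them via
  ``n_exchangeable_h`` (this is how the reference calculators treat a typed
  formula, and is required to reproduce their published outputs);
* contrast = protein SLD - solvent SLD, affine in the D2O buffer fraction,
  so the match point is found by bisection.

All SLDs are reported in units of 1e10 cm^-2.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from scipy.optimize import brentq

from .seqtools import ProteinSequence, atomic_composition, hydrogen_inventory
from .tables import (
    MOLAR_TO_PER_A3,
    RESIDUE_VOLUME,
    SCATTERING_LENGTH,
    WATER_VOLUME,
)

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class ContrastError(ValueError):
    pass


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a simple chemical formula like ``C3H8O3`` into element counts."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise ContrastError(f"cannot parse formula {formula!r}")
        pos = m.end()
        el = m.group(1)
        if el not in SCATTERING_LENGTH:
            raise ContrastError(f"unknown element {el!r} in formula {formula!r}")
        counts[el] = counts.get(el, 0) + (int(m.group(2)) if m.group(2) else 1)
    if pos != len(formula) or not counts:
        raise ContrastError(f"cannot parse formula {formula!r}")
    return counts


@dataclass(frozen=True)
class BufferComponent:
    """One buffer solute: name, formula, molarity (M) and molecular volume (A^3).

    ``n_exchangeable_h`` declares how many of the formula's hydrogens are
    labile and follow the water D2O fraction; default 0 (formula literal).
    """

    name: str
    formula: str
    molarity: float
    volume: float
    n_exchangeable_h: int = 0

    def __post_init__(self):
        if self.molarity < 0:
            raise ContrastError(f"negative molarity for {self.name}")
        if self.volume < 0:
            raise ContrastError(f"negative volume for {self.name}")
        counts = parse_formula(self.formula)
        if self.n_exchangeable_h > counts.get("H", 0):
            raise ContrastError(
                f"{self.name}: more exchangeable H than H in formula"
            )


@dataclass(frozen=True)
class BufferRecipe:
    """Solvent composition: solutes in water prepared at a given D2O fraction.

    ``d2o_buffer_fraction`` is the fraction of the buffer prepared in D2O
    (the mixing convention used at the dialysis bench); because solutes
    displace water, the corresponding *solution* D2O volume fraction is
    ``d2o_buffer_fraction * water_volume_fraction``.
    """

    components: tuple[BufferComponent, ...] = ()
    d2o_buffer_fraction: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.d2o_buffer_fraction <= 1.0:
            raise ContrastError("d2o_buffer_fraction must be in [0, 1]")
        if self.solute_volume_fraction >= 1.0:
            raise ContrastError("total solute volume fraction must be < 1")

    @property
    def solute_volume_fraction(self) -> float:
        return sum(
            c.molarity * MOLAR_TO_PER_A3 * c.volume for c in self.components
        )

    @property
    def water_volume_fraction(self) -> float:
        return 1.0 - self.solute_volume_fraction

    @property
    def solvent_d2o_fraction(self) -> float:
        """D2O as a volume fraction of the whole solution."""
        return self.d2o_buffer_fraction * self.water_volume_fraction

    def with_d2o_fraction(self, f: float) -> "BufferRecipe":
        return replace(self, d2o_buffer_fraction=f)


@dataclass(frozen=True)
class ContrastSpec:
    """Isotopic state of a protein for SLD purposes.

    ``deuteration_nonexchangeable`` (d) is the fraction of non-exchangeable
    (carbon-bound) H replaced by D during expression;
    ``exchangeable_accessibility`` (x) the fraction of labile H that actually
    exchange with the solvent.  The molecular volume defaults to the
    composition estimate from the embedded residue-volume table.
    """

    sequence: ProteinSequence
    deuteration_nonexchangeable: float = 0.0
    exchangeable_accessibility: float = 0.9
    molecular_volume: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.deuteration_nonexchangeable <= 1.0:
            raise ContrastError("deuteration fraction must be in [0, 1]")
        if not 0.0 <= self.exchangeable_accessibility <= 1.0:
            raise ContrastError("exchangeable accessibility must be in [0, 1]")
        if self.molecular_volume is not None and self.molecular_volume <= 0:
            raise ContrastError("molecular volume must be positive")

    @property
    def volume(self) -> float:
        if self.molecular_volume is not None:
            return self.molecular_volume
        return estimate_volume(self.sequence)


@dataclass(frozen=True)
class SldResult:
    sld: float                 # 1e10 cm^-2
    contrast: float | None = None
    provenance: Mapping = field(default_factory=dict)


def estimate_volume(
    seq: ProteinSequence, volume_table: Mapping[str, float] | None = None
) -> float:
    """Molecular volume (A^3) from composition, plus one terminal water."""
    table = volume_table or RESIDUE_VOLUME
    return sum(table[a] for a in seq.residues) + 22.0


def _b_h(fraction_d: float) -> float:
    bH, bD = SCATTERING_LENGTH["H"], SCATTERING_LENGTH["D"]
    return (1.0 - fraction_d) * bH + fraction_d * bD


def solvent_sld(buffer: BufferRecipe) -> SldResult:
    """Scattering-length density of the solvent (water + solutes), 1e10 cm^-2."""
    fD = buffer.d2o_buffer_fraction
    b_water = 2.0 * _b_h(fD) + SCATTERING_LENGTH["O"]
    total = buffer.water_volume_fraction / WATER_VOLUME * b_water
    for comp in buffer.components:
        counts = parse_formula(comp.formula)
        b = sum(
            n * SCATTERING_LENGTH[el] for el, n in counts.items() if el != "H"
        )
        n_h = counts.get("H", 0)
        n_lab = comp.n_exchangeable_h
        b += (n_h - n_lab) * SCATTERING_LENGTH["H"] + n_lab * _b_h(fD)
        total += comp.molarity * MOLAR_TO_PER_A3 * b
    return SldResult(
        sld=total * 10.0,
        provenance={
            "d2o_buffer_fraction": fD,
            "solvent_d2o_fraction": buffer.solvent_d2o_fraction,
            "water_volume_fraction": buffer.water_volume_fraction,
        },
    )


def protein_sld(spec: ContrastSpec, solvent_d2o_fraction: float) -> SldResult:
    """Protein SLD with isotope substitution, 1e10 cm^-2.

    ``solvent_d2o_fraction`` here is the D fraction of the *water* the
    protein equilibrates with (equal to the buffer-mixing fraction when the
    two stock buffers differ only in water isotope).
    """
    atoms = atomic_composition(spec.sequence)
    hinv = hydrogen_inventory(spec.sequence)
    d = spec.deuteration_nonexchangeable
    x = spec.exchangeable_accessibility
    b = sum(
        n * SCATTERING_LENGTH[el] for el, n in atoms.items() if el != "H"
    )
    b += hinv.n_h_nonexchangeable * _b_h(d)
    b += hinv.n_h_exchangeable * _b_h(x * solvent_d2o_fraction)
    return SldResult(
        sld=b / spec.volume * 10.0,
        provenance={
            "deuteration_nonexchangeable": d,
            "exchangeable_accessibility": x,
            "solvent_d2o_fraction": solvent_d2o_fraction,
            "molecular_volume": spec.volume,
            "n_h_exchangeable": hinv.n_h_exchangeable,
            "n_h_nonexchangeable": hinv.n_h_nonexchangeable,
        },
    )


def contrast(spec: ContrastSpec, buffer: BufferRecipe) -> SldResult:
    """Contrast (protein SLD - solvent SLD) of a protein in a buffer."""
    s = solvent_sld(buffer)
    p = protein_sld(spec, buffer.d2o_buffer_fraction)
    return SldResult(
        sld=p.sld,
        contrast=p.sld - s.sld,
        provenance={
            "protein": dict(p.provenance),
            "solvent": dict(s.provenance),
            "solvent_sld": s.sld,
        },
    )


@dataclass(frozen=True)
class MatchPoint:
    d2o_buffer_fraction: float | None
    solvent_d2o_fraction: float | None
    matchable: bool
    contrast_h2o: float
    contrast_d2o: float


def match_point(
    spec: ContrastSpec,
    buffer: BufferRecipe,
    tol: float = 1e-4,
) -> MatchPoint:
    """D2O-buffer fraction at which the protein's contrast vanishes.

    The contrast is monotone (affine) in the buffer-mixing fraction, so the
    root is bracketed on [0, 1] and bisected to |contrast| < ``tol``
    (1e10 cm^-2).  If the contrast does not change sign on [0, 1], the
    protein is unmatchable in water and both endpoint contrasts are reported.
    """
    def f(frac: float) -> float:
        return contrast(spec, buffer.with_d2o_fraction(frac)).contrast

    c0, c1 = f(0.0), f(1.0)
    if c0 == 0.0 or c1 == 0.0 or (c0 < 0) != (c1 < 0):
        root = brentq(f, 0.0, 1.0, xtol=tol / max(abs(c1 - c0), 1.0))
        return MatchPoint(
            d2o_buffer_fraction=root,
            solvent_d2o_fraction=buffer.with_d2o_fraction(root).solvent_d2o_fraction,
            matchable=True,
            contrast_h2o=c0,
            contrast_d2o=c1,
        )
    return MatchPoint(
        d2o_buffer_fraction=None,
        solvent_d2o_fraction=None,
        matchable=False,
        contrast_h2o=c0,
        contrast_d2o=c1,
    )


@dataclass(frozen=True)
class DialysisResult:
    per_step_factors: tuple[float, ...]          # bath/sample convention
    total_factor: float
    residual_initial_percent: float
    per_step_factors_inclusive: tuple[float, ...]  # (bath+sample)/sample
    total_factor_inclusive: float


def dialysis_dilution(
    sample_volume: float, exchanges: Sequence[float]
) -> DialysisResult:
    """Dilution bookkeeping for sequential equilibrium dialysis.

    Two conventions are reported: per-step factor = bath/sample (so two 25x
    baths give 625) and the inclusive convention (bath+sample)/sample used
    when quoting total-over-initial dilution.
    """
    if sample_volume <= 0 or any(v <= 0 for v in exchanges):
        raise ContrastError("sample and bath volumes must be positive")
    if not exchanges:
        raise ContrastError("at least one exchange required")
    factors = tuple(v / sample_volume for v in exchanges)
    total = 1.0
    for fct in factors:
        total *= fct
    inclusive = tuple((v + sample_volume) / sample_volume for v in exchanges)
    total_inc = 1.0
    for fct in inclusive:
        total_inc *= fct
    return DialysisResult(
        per_step_factors=factors,
        total_factor=total,
        residual_initial_percent=100.0 / total,
        per_step_factors_inclusive=inclusive,
        total_factor_inclusive=total_inc,
    )


def glycerol_component(percent_v_v: float) -> BufferComponent:
    """Glycerol specified in %(v/v), using its 121.4 A^3 molecular volume."""
    molarity = percent_v_v / 100.0 / (MOLAR_TO_PER_A3 * 121.4)
    return BufferComponent("glycerol", "C3H8O3", molarity, 121.4)


#: default solute molecular volumes, A^3 (KCl from Pauling ionic volumes;
#: organics from crystal density estimates)
SOLUTE_VOLUMES = {"KCl": 34.7, "HEPES": 310.0, "DTT": 210.0, "NaCl": 27.0}


def standard_buffer(
    glycerol_percent: float = 0.0,
    kcl_mm: float = 0.0,
    hepes_mm: float = 0.0,
    dtt_mm: float = 0.0,
    d2o_buffer_fraction: float = 0.0,
) -> BufferRecipe:
    """Convenience constructor for the glycerol/KCl/HEPES/DTT buffers."""
    comps = []
    if glycerol_percent:
        comps.append(glycerol_component(glycerol_percent))
    if kcl_mm:
        comps.append(BufferComponent("KCl", "KCl", kcl_mm / 1000.0, SOLUTE_VOLUMES["KCl"]))
    if hepes_mm:
        comps.append(
            BufferComponent("HEPES", "C8H18N2O4S", hepes_mm / 1000.0, SOLUTE_VOLUMES["HEPES"])
        )
    if dtt_mm:
        comps.append(
            BufferComponent("DTT", "C4H10O2S2", dtt_mm / 1000.0, SOLUTE_VOLUMES["DTT"])
        )
    return BufferRecipe(components=tuple(comps), d2o_buffer_fraction=d2o_buffer_fraction)
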