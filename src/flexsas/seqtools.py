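"""Protein sequence computations.

Composition and proteome-normalised enrichment profiling, sliding-window
target-residue fractions, average mass / extinction coefficient, and the
hydrogen inventory needed for neutron contrast work.  Positions are 1-based
and intervals closed, following the residue-numbering convention of the
structural literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .tables import (
    AMINO_ACIDS,
    EPSILON_CYSTINE,
    EPSILON_TRP,
    EPSILON_TYR,
    RESIDUE_EXCH_H,
    RESIDUE_FORMULA,
    RESIDUE_MASS,
    WATER_MASS,
)

INFINITE_DEPLETION = "infinite_depletion"
UNDEFINED_ENRICHMENT = "undefined"


class SequenceError(ValueError):
    """Raised for invalid residues, regions or window parameters."""


@dataclass(frozen=True)
class ProteinSequence:
    """A validated protein sequence of canonical one-letter codes."""

    id: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise SequenceError(f"sequence {self.id!r} is empty")
        bad = sorted({c for c in self.residues if c not in AMINO_ACIDS})
        if bad:
            raise SequenceError(
                f"sequence {self.id!r} contains non-canonical codes: {''.join(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def region(self, start: int, end: int) -> str:
        """Residues of the 1-based closed interval [start, end]."""
        if not (1 <= start <= end <= len(self)):
            raise SequenceError(
                f"region {start}-{end} outside sequence 1-{len(self)}"
            )
        return self.residues[start - 1:end]


@dataclass(frozen=True)
class CompositionProfile:
    proportions: Mapping[str, float]
    counts: Mapping[str, int]
    region: tuple[int, int]

    @property
    def length(self) -> int:
        return self.region[1] - self.region[0] + 1


@dataclass(frozen=True)
class EnrichmentProfile:
    """Per-amino-acid query/reference proportion ratios.

    A residue type absent from the query but present in the reference is
    flagged ``INFINITE_DEPLETION`` (the grey-bar convention of enrichment
    histograms); a nonzero query fraction over a zero reference fraction is
    flagged ``UNDEFINED_ENRICHMENT`` rather than reported as a number.
    """

    ratios: Mapping[str, float | str]
    reference_id: str


@dataclass(frozen=True)
class PhyschemSummary:
    average_mass_kda: float
    epsilon_molar: float           # M^-1 cm^-1, all cysteines reduced
    epsilon_molar_cystine: float   # M^-1 cm^-1, all cysteines as cystine
    epsilon_mass: float            # ml mg^-1 cm^-1, reduced-Cys convention
    n_trp: int
    n_tyr: int
    n_cys: int
    n_copies: int


@dataclass(frozen=True)
class HydrogenInventory:
    n_h_total: int
    n_h_exchangeable: int
    per_residue_table: Mapping[str, tuple[int, int]] = field(repr=False, default=None)

    @property
    def n_h_nonexchangeable(self) -> int:
        return self.n_h_total - self.n_h_exchangeable


def read_fasta(path: str | Path, permissive: bool = False) -> list[ProteinSequence]:
    """Read a (possibly multi-record, line-wrapped) protein FASTA file.

    In strict mode (default) non-canonical codes raise; with
    ``permissive=True`` they are dropped with a warning.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    out = []
    for rec in records:
        seq = str(rec.seq).upper().replace(" ", "")
        if permissive:
            kept = "".join(c for c in seq if c in AMINO_ACIDS)
            if kept != seq:
                import warnings

                dropped = sorted({c for c in seq if c not in AMINO_ACIDS})
                warnings.warn(
                    f"{rec.id}: dropped non-canonical codes {''.join(dropped)}"
                )
            seq = kept
        out.append(ProteinSequence(id=rec.id, residues=seq))
    return out


def sfpq_sequence(construct: bool = False) -> ProteinSequence:
    """The bundled full-length human SFPQ sequence (UniProt P23246, 707 aa).

    With ``construct=True`` the expressed TEV-cleaved construct is returned
    (an N-terminal Gly-Ser scar preceding residues 1-707, 709 aa), which is
    the species whose chemical-composition mass is reported for the purified
    protein.  The bundled copy is cross-validated against the published
    chemical-composition mass and A280 extinction coefficient.
    """
    with resources.files("flexsas.data").joinpath("sfpq_p23246.fasta").open() as fh:
        rec = next(SeqIO.parse(fh, "fasta"))
    seq = str(rec.seq)
    if construct:
        return ProteinSequence(id="SFPQ_construct_GS", residues="GS" + seq)
    return ProteinSequence(id=rec.id, residues=seq)


def composition(
    seq: ProteinSequence, region: tuple[int, int] | None = None
) -> CompositionProfile:
    """Amino-acid counts and fractions over a 1-based closed region."""
    if region is None:
        region = (1, len(seq))
    sub = seq.region(*region)
    counts = {aa: sub.count(aa) for aa in AMINO_ACIDS}
    n = len(sub)
    props = {aa: counts[aa] / n for aa in AMINO_ACIDS}
    return CompositionProfile(proportions=props, counts=counts, region=tuple(region))


def enrichment(
    query: CompositionProfile, reference: CompositionProfile, reference_id: str = "reference"
) -> EnrichmentProfile:
    """Query fractions divided by reference (e.g. whole-proteome) fractions."""
    ratios: dict[str, float | str] = {}
    for aa in AMINO_ACIDS:
        q, r = query.proportions[aa], reference.proportions[aa]
        if r == 0.0:
            ratios[aa] = 1.0 if q == 0.0 else UNDEFINED_ENRICHMENT
        elif q == 0.0:
            ratios[aa] = INFINITE_DEPLETION
        else:
            ratios[aa] = q / r
    return EnrichmentProfile(ratios=ratios, reference_id=reference_id)


def sliding_window(
    seq: ProteinSequence, targets: Iterable[str], width: int = 30
) -> dict:
    """Fraction of target residues in every width-residue window.

    Values are indexed by the 1-based window *start* position (documented
    convention; a window starting at i covers residues i .. i+width-1), so the
    output has L - width + 1 values.
    """
    targets = set(targets)
    bad = targets - set(AMINO_ACIDS)
    if bad:
        raise SequenceError(f"unknown target residues: {sorted(bad)}")
    L = len(seq)
    if width < 1:
        raise SequenceError("window width must be >= 1")
    if width > L:
        raise SequenceError(f"window width {width} exceeds sequence length {L}")
    hits = [1 if c in targets else 0 for c in seq.residues]
    csum = [0]
    for h in hits:
        csum.append(csum[-1] + h)
    values = [
        (csum[i + width] - csum[i]) / width for i in range(L - width + 1)
    ]
    return {
        "start_positions": list(range(1, L - width + 2)),
        "values": values,
        "width": width,
        "targets": sorted(targets),
        "convention": "window-start-indexed, 1-based",
    }


def physchem(seq: ProteinSequence, n_copies: int = 1) -> PhyschemSummary:
    """Average mass and A280 extinction coefficient by the composition method.

    Mass per chain is the residue-mass sum plus one water; epsilon uses
    5500*nW + 1490*nY per chain (reduced cysteines), with the
    cystine-inclusive alternative (+125 per disulfide-paired Cys pair)
    reported alongside.
    """
    if n_copies < 1:
        raise SequenceError("n_copies must be >= 1")
    chain_mass = sum(RESIDUE_MASS[a] for a in seq.residues) + WATER_MASS
    n_trp = seq.residues.count("W")
    n_tyr = seq.residues.count("Y")
    n_cys = seq.residues.count("C")
    eps_reduced = (EPSILON_TRP * n_trp + EPSILON_TYR * n_tyr) * n_copies
    eps_cystine = eps_reduced + EPSILON_CYSTINE * (n_cys // 2) * n_copies
    total_mass = chain_mass * n_copies
    return PhyschemSummary(
        average_mass_kda=total_mass / 1000.0,
        epsilon_molar=eps_reduced,
        epsilon_molar_cystine=eps_cystine,
        epsilon_mass=eps_reduced / total_mass,
        n_trp=n_trp * n_copies,
        n_tyr=n_tyr * n_copies,
        n_cys=n_cys * n_copies,
        n_copies=n_copies,
    )


def hydrogen_inventory(seq: ProteinSequence) -> HydrogenInventory:
    """Total and exchangeable hydrogen counts for one chain.

    Uses the fixed per-residue table in :mod:`flexsas.tables` (pH ~7
    ionization; proline contributes no backbone amide H) plus one terminal
    water per chain whose two hydrogens are both exchangeable.
    """
    total = sum(RESIDUE_FORMULA[a][1] for a in seq.residues) + 2
    exch = sum(RESIDUE_EXCH_H[a] for a in seq.residues) + 2
    table = {
        aa: (RESIDUE_FORMULA[aa][1], RESIDUE_EXCH_H[aa]) for aa in AMINO_ACIDS
    }
    return HydrogenInventory(
        n_h_total=total, n_h_exchangeable=exch, per_residue_table=table
    )


def atomic_composition(seq: ProteinSequence) -> dict[str, int]:
    """Element counts (C,H,N,O,S) for one chain including terminal water."""
    c = h = n = o = s = 0
    for a in seq.residues:
        C, H, N, O, S = RESIDUE_FORMULA[a]
        c += C; h += H; n += N; o += O; s += S
    return {"C": c, "H": h + 2, "N": n, "O": o + 1, "S": s}
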