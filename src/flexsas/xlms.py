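"""Cross-linking mass-spectrometry restraint interpretation.

Consumes identified lysine-lysine cross-link tables (as exported by
identification software), classifies each link against a named domain map
(IDR vs folded-core region pairs, with same-peptide links in their own
category), and scores distance feasibility against conformer ensembles
using a configurable C-alpha--C-alpha cutoff (default 30 A, appropriate for
the DSSO spacer plus two lysine side chains).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ensemble import EnsemblePool
from .seqtools import ProteinSequence

SAME_PEPTIDE_CATEGORY = "same-peptide"


class XlmsError(ValueError):
    pass


@dataclass(frozen=True)
class DomainMap:
    """Named, non-overlapping 1-based closed residue intervals."""

    regions: Mapping[str, tuple[int, int]]
    length: int

    def __post_init__(self):
        ivs = sorted(self.regions.values())
        for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
            if a2 <= b1:
                raise XlmsError("domain intervals overlap")
        for name, (a, b) in self.regions.items():
            if not (1 <= a <= b <= self.length):
                raise XlmsError(
                    f"region {name} {a}-{b} outside sequence 1-{self.length}")

    def region_of(self, pos: int) -> str | None:
        for name, (a, b) in self.regions.items():
            if a <= pos <= b:
                return name
        return None


def sfpq_domain_map() -> DomainMap:
    """The standard SFPQ annotation: N-IDR, folded DBHS core, C-IDR."""
    return DomainMap(
        regions={"N-IDR": (1, 275), "DBHS-core": (276, 598),
                 "C-IDR": (599, 707)},
        length=707,
    )


@dataclass(frozen=True)
class CrossLink:
    residue_a: int
    residue_b: int
    count: int = 1
    same_peptide: bool = False
    score: float | None = None

    def __post_init__(self):
        if self.residue_a < 1 or self.residue_b < 1:
            raise XlmsError("residue positions are 1-based and positive")

    @property
    def pair(self) -> tuple[int, int]:
        return tuple(sorted((self.residue_a, self.residue_b)))


DEFAULT_COLUMNS = {"residue_a": "residue_a", "residue_b": "residue_b",
                   "same_peptide": "same_peptide", "score": "score"}


def read_links(path: str | Path, seq: ProteinSequence | None = None,
               column_map: Mapping[str, str] | None = None,
               strict: bool = True) -> list[CrossLink]:
    """Read a CSV/TSV link table; duplicates collapse with occurrence counts.

    ``column_map`` maps the canonical names (residue_a, residue_b,
    same_peptide, score) onto the table's column headers.  In strict mode
    each linked position must be a lysine or the protein N-terminus of the
    supplied sequence (DSSO chemistry).
    """
    cols = {**DEFAULT_COLUMNS, **(column_map or {})}
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    for key in ("residue_a", "residue_b"):
        if cols[key] not in df.columns:
            raise XlmsError(f"column {cols[key]!r} missing from {path}")
    collapsed: dict[tuple, dict] = {}
    for row_no, row in df.iterrows():
        a = int(row[cols["residue_a"]])
        b = int(row[cols["residue_b"]])
        same = bool(row[cols["same_peptide"]]) if cols["same_peptide"] in df.columns else False
        score = float(row[cols["score"]]) if cols["score"] in df.columns and not pd.isna(row[cols["score"]]) else None
        if seq is not None:
            for pos in (a, b):
                if pos > len(seq):
                    raise XlmsError(
                        f"row {row_no}: position {pos} beyond sequence "
                        f"length {len(seq)}")
                if strict and pos != 1 and seq.residues[pos - 1] != "K":
                    raise XlmsError(
                        f"row {row_no}: position {pos} is "
                        f"{seq.residues[pos - 1]}, not K (strict mode)")
        key = (tuple(sorted((a, b))), same)
        if key in collapsed:
            collapsed[key]["count"] += 1
        else:
            collapsed[key] = {"a": a, "b": b, "same": same, "score": score,
                              "count": 1}
    return [
        CrossLink(residue_a=v["a"], residue_b=v["b"], count=v["count"],
                  same_peptide=v["same"], score=v["score"])
        for v in collapsed.values()
    ]


def write_links(links: Sequence[CrossLink], path: str | Path) -> None:
    rows = []
    for ln in links:
        for _ in range(ln.count):
            rows.append({"residue_a": ln.residue_a, "residue_b": ln.residue_b,
                         "same_peptide": ln.same_peptide, "score": ln.score})
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def classify_links(links: Sequence[CrossLink], dmap: DomainMap) -> dict:
    """Label every link by its (ordered) region pair.

    Classification is symmetric in endpoint order: the category is the
    region pair sorted by region start.  Same-peptide links always fall in
    the dedicated same-peptide category regardless of regions.
    """
    per_link = []
    counts: dict[str, int] = {}
    for ln in links:
        if ln.same_peptide:
            cat = SAME_PEPTIDE_CATEGORY
        else:
            ra = dmap.region_of(ln.residue_a)
            rb = dmap.region_of(ln.residue_b)
            for pos, rr in ((ln.residue_a, ra), (ln.residue_b, rb)):
                if rr is None:
                    raise XlmsError(f"residue {pos} not covered by domain map")
            pair = sorted((ra, rb), key=lambda n: dmap.regions[n][0])
            cat = f"{pair[0]}--{pair[1]}"
        per_link.append({"link": ln, "category": cat})
        counts[cat] = counts.get(cat, 0) + 1
    return {"per_link": per_link, "category_counts": counts,
            "n_links": len(links)}


def link_feasibility(links: Sequence[CrossLink], ensemble: EnsemblePool,
                     calpha_cutoff: float = 30.0,
                     dmap: DomainMap | None = None) -> dict:
    """Distance-feasibility statistics of links over a conformer ensemble.

    For each link, the C-alpha--C-alpha distance is evaluated in every
    conformer; in homodimers a linked residue pair maps onto several
    chain-assignment combinations and the minimum distance is used, flagged
    ambiguous.  Reported per link: min/mean/median distance and the fraction
    of conformers within ``calpha_cutoff``; per region pair (when a domain
    map is given): the aggregate satisfaction fraction.
    """
    if not ensemble.conformers:
        raise XlmsError("empty ensemble")
    model0 = ensemble.conformers[0]
    pos_index: dict[int, np.ndarray] = {}
    for rid in np.unique(model0.residue_ids):
        pos_index[int(rid)] = np.flatnonzero(model0.residue_ids == rid)
    per_link = []
    for ln in links:
        for pos in (ln.residue_a, ln.residue_b):
            if pos not in pos_index:
                raise XlmsError(f"residue {pos} not covered by the models")
        ia, ib = pos_index[ln.residue_a], pos_index[ln.residue_b]
        ambiguous = len(ia) > 1 or len(ib) > 1
        dists = np.empty(len(ensemble.conformers))
        for k, conf in enumerate(ensemble.conformers):
            diff = conf.coords[ia][:, None, :] - conf.coords[ib][None, :, :]
            d = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
            if ln.residue_a == ln.residue_b:
                dists[k] = 0.0
            else:
                dists[k] = float(d.min())
        frac = float(np.mean(dists <= calpha_cutoff))
        entry = {
            "link": ln,
            "min": float(dists.min()), "mean": float(dists.mean()),
            "median": float(np.median(dists)),
            "satisfied_fraction": frac,
            "ambiguous": ambiguous,
        }
        if dmap is not None:
            cat = classify_links([ln], dmap)["per_link"][0]["category"]
            entry["category"] = cat
        per_link.append(entry)
    out = {"per_link": per_link, "calpha_cutoff": calpha_cutoff}
    if dmap is not None:
        agg: dict[str, list[float]] = {}
        for e in per_link:
            agg.setdefault(e["category"], []).append(e["satisfied_fraction"])
        out["per_category"] = {k: float(np.mean(v)) for k, v in agg.items()}
    return out
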