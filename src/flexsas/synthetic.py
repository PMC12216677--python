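"""Seeded generators for every input the analysis pipeline consumes.

Scattering phantoms with analytic ground truth (sphere, pure Guinier, Debye
coil, custom P(r), conformer mixtures), SEC elution frame series with buffer
frames and optional Rg drift, random sequences of controlled composition and
toy cross-link tables from a known structure.  Every generator is a pure
function of (spec, seed) and emits a ground-truth record sufficient to score
the downstream analysis without reference to generator internals.

Noise model
-----------
sigma(q) = a * I(q) + b * sqrt(I(q) + c), emulating a relative error floor
plus counting statistics.  Defaults: a = 0.01 (1% floor), b = c = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .ensemble import ConformerModel, debye_profile
from .sas import FrameSeries, ScatteringCurve, _ift_design
from .seqtools import AMINO_ACIDS, ProteinSequence


class SyntheticError(ValueError):
    pass


# ---------------------------------------------------------------------------
# analytic reference forms


def sphere_intensity(q: np.ndarray, radius: float, i0: float = 1.0) -> np.ndarray:
    """Form factor of a homogeneous sphere; I(0) = i0, Rg = sqrt(3/5) R."""
    qr = np.asarray(q, float) * radius
    amp = np.ones_like(qr)
    nz = qr != 0
    amp[nz] = 3.0 * (np.sin(qr[nz]) - qr[nz] * np.cos(qr[nz])) / qr[nz] ** 3
    return i0 * amp ** 2


def guinier_intensity(q: np.ndarray, rg: float, i0: float = 1.0) -> np.ndarray:
    return i0 * np.exp(-(np.asarray(q, float) * rg) ** 2 / 3.0)


def debye_coil_intensity(q: np.ndarray, rg: float, i0: float = 1.0) -> np.ndarray:
    """Debye Gaussian-coil function; plateaus at 2/x for large x = (qRg)^2."""
    x = (np.asarray(q, float) * rg) ** 2
    out = np.ones_like(x)
    nz = x > 1e-12
    out[nz] = 2.0 * (np.exp(-x[nz]) + x[nz] - 1.0) / x[nz] ** 2
    return i0 * out


def sphere_pr(r: np.ndarray, radius: float) -> np.ndarray:
    """Closed-form distance distribution of a sphere, normalized to max 1."""
    r = np.asarray(r, float)
    u = r / radius
    p = np.where(
        (r >= 0) & (r <= 2 * radius),
        r ** 2 * (1.0 - 0.75 * u + u ** 3 / 16.0),
        0.0,
    )
    m = p.max()
    return p / m if m > 0 else p


def pr_to_intensity(r: np.ndarray, p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Forward transform I(q) = 4 pi int P(r) sinc(qr) dr (trapezoid)."""
    r = np.asarray(r, float)
    if r[0] != 0.0:
        raise SyntheticError("P(r) grid must start at r = 0")
    K = _ift_design(np.asarray(q, float), r)
    return K @ np.asarray(p, float)


# ---------------------------------------------------------------------------
# phantom curves


DEFAULT_Q_GRID = np.linspace(0.005, 0.5, 400)


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of a synthetic scattering curve with known truth.

    kind: sphere | guinier | coil | pr_custom | ensemble_mixture.
    ``radius``/``rg`` parametrize the analytic kinds; ``pr_table`` is an
    (r, p) pair for pr_custom; ``members``/``weights`` give the conformer
    mixture.  Noise: sigma = a*I + b*sqrt(I + c).
    """

    kind: str
    radius: float | None = None
    rg: float | None = None
    pr_table: tuple | None = None
    members: tuple | None = None       # ConformerModel, ...
    weights: tuple | None = None
    i0: float = 1.0
    q_grid: np.ndarray = field(default_factory=lambda: DEFAULT_Q_GRID.copy())
    noise_a: float = 0.01
    noise_b: float = 0.0
    noise_c: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("sphere", "guinier", "coil", "pr_custom",
                             "ensemble_mixture"):
            raise SyntheticError(f"unknown phantom kind {self.kind!r}")
        if min(self.noise_a, self.noise_b, self.noise_c) < 0:
            raise SyntheticError("noise parameters must be >= 0")
        if self.kind == "ensemble_mixture":
            if not self.members or not self.weights:
                raise SyntheticError("mixture needs members and weights")
            if abs(sum(self.weights) - 1.0) > 1e-9:
                raise SyntheticError("mixture weights must sum to 1")


def _apply_noise(i: np.ndarray, spec: PhantomSpec,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    sigma = spec.noise_a * np.abs(i) + spec.noise_b * np.sqrt(np.abs(i) + spec.noise_c)
    floor = 1e-8 * float(np.max(np.abs(i)))
    sigma = np.maximum(sigma, floor if floor > 0 else 1e-12)
    noisy = i + rng.normal(0.0, sigma) if (spec.noise_a or spec.noise_b) else i.copy()
    return noisy, sigma


def make_phantom(spec: PhantomSpec) -> tuple[ScatteringCurve, dict]:
    """Generate a noisy analytic phantom plus its ground-truth record."""
    q = np.asarray(spec.q_grid, float)
    rng = np.random.default_rng(spec.seed)
    truth: dict = {"kind": spec.kind, "i0": spec.i0, "seed": spec.seed}
    if spec.kind == "sphere":
        if not spec.radius or spec.radius <= 0:
            raise SyntheticError("sphere phantom needs a positive radius")
        i = sphere_intensity(q, spec.radius, spec.i0)
        truth.update(radius=spec.radius, rg=np.sqrt(3.0 / 5.0) * spec.radius,
                     dmax=2.0 * spec.radius)
    elif spec.kind == "guinier":
        if not spec.rg or spec.rg <= 0:
            raise SyntheticError("guinier phantom needs a positive rg")
        i = guinier_intensity(q, spec.rg, spec.i0)
        truth.update(rg=spec.rg)
    elif spec.kind == "coil":
        if not spec.rg or spec.rg <= 0:
            raise SyntheticError("coil phantom needs a positive rg")
        i = debye_coil_intensity(q, spec.rg, spec.i0)
        truth.update(rg=spec.rg)
    elif spec.kind == "pr_custom":
        if spec.pr_table is None:
            raise SyntheticError("pr_custom phantom needs pr_table")
        r, p = (np.asarray(v, float) for v in spec.pr_table)
        i = pr_to_intensity(r, p, q)
        scale = spec.i0 / i[0] if i[0] != 0 else 1.0
        i = i * scale
        dr = r[1] - r[0]
        m0 = np.trapezoid(p, r)
        rg = float(np.sqrt(np.trapezoid(r ** 2 * p, r) / (2.0 * m0)))
        truth.update(r_grid=r, p=p * scale, dmax=float(r[-1]), rg=rg)
    else:  # ensemble_mixture
        profiles = [debye_profile(m, q).i for m in spec.members]
        i = np.zeros_like(q)
        for w, prof in zip(spec.weights, profiles):
            i = i + w * prof / prof[0]
        i = spec.i0 * i / i[0]
        truth.update(
            weights=tuple(spec.weights),
            member_rg=tuple(m.rg for m in spec.members),
            member_dmax=tuple(m.dmax_pair for m in spec.members),
        )
    noisy, sigma = _apply_noise(i, spec, rng)
    curve = ScatteringCurve(q, noisy, sigma,
                            metadata={"phantom": spec.kind, "seed": spec.seed})
    truth["intensity_clean"] = i
    return curve, truth


# ---------------------------------------------------------------------------
# SEC frame series


def make_sec_series(elution_profile: Sequence[float], phantom: PhantomSpec,
                    buffer_level: float = 0.01,
                    rg_drift: tuple[float, float] | None = None,
                    seed: int = 0) -> tuple[FrameSeries, dict]:
    """Emulate a SEC-SAS frame series with buffer frames and optional drift.

    Each frame is concentration * phantom intensity + a flat buffer baseline
    + noise.  ``rg_drift=(rg_start, rg_end)`` linearly interpolates between
    two phantoms of the same kind across the *eluting* frames, emulating
    larger conformers eluting first.  Roles in the ground truth label frames
    with zero concentration as buffer.
    """
    conc = np.asarray(elution_profile, float)
    if conc.size < 3:
        raise SyntheticError("need at least 3 frames")
    if np.all(conc == 0):
        raise SyntheticError("all-zero elution profile")
    if np.any(conc < 0):
        raise SyntheticError("negative concentrations")
    rng = np.random.default_rng(seed)
    q = np.asarray(phantom.q_grid, float)
    base_i = make_phantom(
        PhantomSpec(**{**phantom.__dict__, "noise_a": 0.0, "noise_b": 0.0})
    )[1]["intensity_clean"]
    eluting = np.flatnonzero(conc > 0)
    frames, roles, frame_rg = [], [], []
    for k, c in enumerate(conc):
        if rg_drift is not None and c > 0:
            t = (np.searchsorted(eluting, k) / max(len(eluting) - 1, 1))
            rg_k = rg_drift[0] + t * (rg_drift[1] - rg_drift[0])
            kind_kwargs = dict(phantom.__dict__)
            kind_kwargs.update(noise_a=0.0, noise_b=0.0)
            if phantom.kind == "sphere":
                kind_kwargs["radius"] = rg_k / np.sqrt(3.0 / 5.0)
            else:
                kind_kwargs["rg"] = rg_k
            i_k = make_phantom(PhantomSpec(**kind_kwargs))[1]["intensity_clean"]
        else:
            rg_k = None
            i_k = base_i
        clean = c * i_k + buffer_level
        sigma = phantom.noise_a * np.abs(clean) + phantom.noise_b * np.sqrt(
            np.abs(clean) + phantom.noise_c)
        sigma = np.maximum(sigma, 1e-8 * max(float(np.max(np.abs(clean))), 1e-12))
        noisy = clean + rng.normal(0.0, sigma)
        frames.append(ScatteringCurve(q, noisy, sigma,
                                      metadata={"frame": k, "conc": float(c)}))
        roles.append("buffer" if c == 0 else "sample")
        frame_rg.append(rg_k)
    truth = {
        "concentrations": conc,
        "roles": list(roles),
        "buffer_level": buffer_level,
        "rg_drift": rg_drift,
        "frame_rg": frame_rg,
        "phantom_truth": make_phantom(
            PhantomSpec(**{**phantom.__dict__, "noise_a": 0.0, "noise_b": 0.0})
        )[1],
    }
    return FrameSeries(frames=frames, roles=roles), truth


# ---------------------------------------------------------------------------
# sequences


def make_sequence(length: int, composition: Mapping[str, float],
                  seed: int = 0, seq_id: str = "synthetic") -> ProteinSequence:
    """Random sequence drawn from target amino-acid fractions (multinomial)."""
    if length < 1:
        raise SyntheticError("length must be >= 1")
    aas = sorted(composition)
    bad = [a for a in aas if a not in AMINO_ACIDS]
    if bad:
        raise SyntheticError(f"unknown amino acids {bad}")
    fracs = np.array([composition[a] for a in aas], float)
    if np.any(fracs < 0) or abs(fracs.sum() - 1.0) > 1e-9:
        raise SyntheticError("composition fractions must be >= 0 and sum to 1")
    rng = np.random.default_rng(seed)
    draws = rng.choice(len(aas), size=length, p=fracs)
    return ProteinSequence(id=seq_id, residues="".join(aas[k] for k in draws))


# ---------------------------------------------------------------------------
# cross-link tables


def make_crosslinks(model: ConformerModel, lysine_positions: Sequence[int],
                    cutoff: float, n_true: int, n_decoy: int,
                    seed: int = 0) -> tuple[list, dict]:
    """Sample true (within cutoff) and decoy (beyond 2x cutoff) K-K links.

    Returns a list of dicts (residue_a, residue_b, label) and a truth record.
    """
    from .xlms import CrossLink

    lys = sorted(set(int(p) for p in lysine_positions))
    pos_to_idx: dict[int, list[int]] = {}
    for i, rid in enumerate(model.residue_ids):
        pos_to_idx.setdefault(int(rid), []).append(i)
    missing = [p for p in lys if p not in pos_to_idx]
    if missing:
        raise SyntheticError(f"lysine positions outside model: {missing}")
    if len(lys) < 2:
        raise SyntheticError("need at least 2 lysine positions")
    pairs_true, pairs_decoy = [], []
    for ii in range(len(lys)):
        for jj in range(ii + 1, len(lys)):
            a, b = lys[ii], lys[jj]
            d = min(
                float(np.linalg.norm(model.coords[x] - model.coords[y]))
                for x in pos_to_idx[a] for y in pos_to_idx[b]
            )
            if d <= cutoff:
                pairs_true.append((a, b, d))
            elif d > 2.0 * cutoff:
                pairs_decoy.append((a, b, d))
    if len(pairs_true) < n_true:
        raise SyntheticError(
            f"only {len(pairs_true)} K-K pairs within {cutoff} A; "
            f"cannot sample {n_true} true links")
    if len(pairs_decoy) < n_decoy:
        raise SyntheticError(
            f"only {len(pairs_decoy)} K-K pairs beyond {2 * cutoff} A; "
            f"cannot sample {n_decoy} decoy links")
    rng = np.random.default_rng(seed)
    chosen_true = [pairs_true[k] for k in
                   rng.choice(len(pairs_true), n_true, replace=False)]
    chosen_decoy = [pairs_decoy[k] for k in
                    rng.choice(len(pairs_decoy), n_decoy, replace=False)]
    links = []
    labels = {}
    for a, b, d in chosen_true:
        links.append(CrossLink(residue_a=a, residue_b=b))
        labels[(a, b)] = "true"
    for a, b, d in chosen_decoy:
        links.append(CrossLink(residue_a=a, residue_b=b))
        labels[(a, b)] = "decoy"
    truth = {"labels": labels, "cutoff": cutoff, "seed": seed,
             "n_true": n_true, "n_decoy": n_decoy}
    return links, truth
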