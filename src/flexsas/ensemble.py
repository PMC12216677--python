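"""Ensemble-optimization modelling of flexible proteins.

The workflow mirrors the random-pool / genetic-algorithm approach used to
interpret scattering from proteins with intrinsically disordered regions:

1. :func:`build_pool` grows self-avoiding C-alpha chains (bond 3.8 A,
   coil-like pseudo-bond-angle sampling, clash rejection) off a rigid folded
   core, giving a pool of sterically plausible conformers;
2. :func:`debye_profile` computes each conformer's scattering profile with
   the Debye double sum over identical dummy-residue form factors;
3. :class:`EnsembleOptimizer` (``fit()``) runs a genetic algorithm over
   fixed-size index multisets, selecting sub-ensembles whose average profile
   fits a target curve; repeated runs are pooled;
4. :func:`flex_metrics` and :func:`compaction_test` compare the selected
   Rg/Dmax distributions with the pool's (geometric mean, Rflex, Rsigma) to
   diagnose compaction or extension.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .sas import ScatteringCurve

BOND_LENGTH = 3.8          # A, consecutive C-alpha distance
CLASH_DISTANCE = 3.0       # A, minimum non-adjacent bead separation
DUMMY_RESIDUE_RG = 2.5     # A, Gaussian dummy-residue form-factor size


class EnsembleError(ValueError):
    pass


# ---------------------------------------------------------------------------
# conformers


@dataclass(frozen=True)
class ConformerModel:
    """A C-alpha bead model: coordinates plus residue/chain/segment labels."""

    coords: np.ndarray                   # (n, 3)
    residue_ids: np.ndarray              # (n,) 1-based residue numbers
    chain_ids: np.ndarray | None = None  # (n,) integer chain index
    segment_labels: np.ndarray | None = None  # 'core' | 'disordered'

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        rid = np.asarray(self.residue_ids, dtype=int)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
            raise EnsembleError("coords must be an (n, 3) array")
        if rid.shape[0] != coords.shape[0]:
            raise EnsembleError("residue_ids must match coords length")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "residue_ids", rid)
        if self.chain_ids is None:
            object.__setattr__(self, "chain_ids",
                               np.zeros(coords.shape[0], dtype=int))
        else:
            object.__setattr__(self, "chain_ids",
                               np.asarray(self.chain_ids, dtype=int))
        if self.segment_labels is None:
            object.__setattr__(self, "segment_labels",
                               np.full(coords.shape[0], "disordered"))

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]

    @property
    def rg(self) -> float:
        c = self.coords - self.coords.mean(axis=0)
        return float(np.sqrt(np.mean(np.sum(c ** 2, axis=1))))

    @property
    def dmax_pair(self) -> float:
        """Maximum pairwise C-alpha distance (the convention used here)."""
        if self.n_beads == 1:
            return 0.0
        return float(np.max(pdist(self.coords)))


# ---------------------------------------------------------------------------
# chain growth

#: three-state pseudo-bond-angle sampler for the coil library: each state is
#: (probability, mean theta deg, sd deg) for the angle between successive
#: C-alpha virtual bonds.  PPII/beta-like extended states dominate, matching
#: the extended character of P/G-rich disordered chains; the compact state
#: keeps locally helical geometries accessible.
COIL_STATES = (
    (0.40, 120.0, 15.0),   # PPII-like
    (0.35, 140.0, 12.0),   # beta/extended
    (0.25, 95.0, 15.0),    # compact/helical
)


def _sample_direction(rng: np.random.Generator, prev: np.ndarray) -> np.ndarray:
    """New virtual-bond unit vector given the previous bond direction."""
    probs = np.array([s[0] for s in COIL_STATES])
    k = rng.choice(len(COIL_STATES), p=probs / probs.sum())
    _, mu, sd = COIL_STATES[k]
    theta = np.deg2rad(rng.normal(mu, sd))
    theta = np.clip(theta, np.deg2rad(60.0), np.deg2rad(175.0))
    phi = rng.uniform(0.0, 2.0 * np.pi)
    # orthonormal frame around prev
    a = np.array([1.0, 0.0, 0.0])
    if abs(prev @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(prev, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(prev, e1)
    # bond angle theta is the angle between -prev and the new bond
    d = -np.cos(theta) * prev + np.sin(theta) * (
        np.cos(phi) * e1 + np.sin(phi) * e2)
    return d / np.linalg.norm(d)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _grow_segment(rng: np.random.Generator, anchor: np.ndarray | None,
                  anchor_prev: np.ndarray | None, n_new: int,
                  existing: np.ndarray, clash: float,
                  max_retries: int) -> list[np.ndarray] | None:
    """Grow ``n_new`` beads from an anchor with vectorized clash rejection.

    ``anchor`` is the bead the segment extends from (None for a free chain,
    whose first bead is placed at the origin and counts toward ``n_new``);
    ``anchor_prev`` defines the incoming bond direction where known.
    ``existing`` holds every bead placed so far.  Returns the new beads only,
    or None once retries are exhausted.  Consecutive beads sit at
    BOND_LENGTH, which exceeds the clash radius, so the clash test can run
    against the full buffer.
    """
    n_exist = existing.shape[0]
    buf = np.empty((n_exist + n_new, 3))
    buf[:n_exist] = existing
    count = n_exist
    new_beads: list[np.ndarray] = []
    c2 = clash * clash
    if anchor is None:
        last = np.zeros(3)
        buf[count] = last
        count += 1
        new_beads.append(last.copy())
        n_new -= 1
        prev_dir = None
    else:
        last = np.asarray(anchor, dtype=float)
        prev_dir = None
        if anchor_prev is not None:
            d = last - np.asarray(anchor_prev, dtype=float)
            nrm = np.linalg.norm(d)
            if nrm > 0:
                prev_dir = d / nrm
    for _ in range(n_new):
        for _attempt in range(max_retries):
            direction = (_random_unit(rng) if prev_dir is None
                         else _sample_direction(rng, prev_dir))
            cand = last + BOND_LENGTH * direction
            if count:
                diff = buf[:count] - cand
                d2 = np.einsum("ij,ij->i", diff, diff)
                if np.any(d2 < c2):
                    continue
            buf[count] = cand
            count += 1
            new_beads.append(cand)
            prev_dir = direction
            last = cand
            break
        else:
            return None
    return new_beads


@dataclass(frozen=True)
class ChainSpec:
    """One chain of the construct: length and optional rigid-core coordinates.

    ``core_coords`` maps 1-based residue number -> (x, y, z) for residues
    that are part of the rigid folded core; all other residues are built as
    disordered.  Disordered runs must be terminal (anchored at a core end or
    forming a fully free chain) -- bridging loops between two core segments
    are out of scope.
    """

    length: int
    core_coords: Mapping[int, Sequence[float]] | None = None

    def disordered_runs(self) -> list[tuple[int, int]]:
        core = set(self.core_coords or {})
        runs, start = [], None
        for pos in range(1, self.length + 1):
            if pos not in core:
                if start is None:
                    start = pos
            elif start is not None:
                runs.append((start, pos - 1))
                start = None
        if start is not None:
            runs.append((start, self.length))
        for a, b in runs:
            if core and a != 1 and b != self.length:
                raise EnsembleError(
                    f"disordered run {a}-{b} is an interior loop; only "
                    "terminal segments are supported")
        return runs


@dataclass
class EnsemblePool:
    """Conformer pool with per-conformer profiles and size distributions."""

    conformers: list[ConformerModel]
    q_grid: np.ndarray
    profiles: np.ndarray          # (n_conformers, n_q)
    seed: int
    n_failures: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def rg_distribution(self) -> np.ndarray:
        return np.array([c.rg for c in self.conformers])

    @property
    def dmax_distribution(self) -> np.ndarray:
        return np.array([c.dmax_pair for c in self.conformers])

    def __len__(self) -> int:
        return len(self.conformers)


def build_conformer(chains: Sequence[ChainSpec], rng: np.random.Generator,
                    clash: float = CLASH_DISTANCE,
                    max_retries: int = 500) -> ConformerModel | None:
    """Build one conformer; None if clash rejection exhausts retries."""
    coords, rids, cids, labels = [], [], [], []
    core_arrays = []
    for ci, chain in enumerate(chains):
        core = chain.core_coords or {}
        for pos in sorted(core):
            core_arrays.append(np.asarray(core[pos], dtype=float))
    existing = np.array(core_arrays) if core_arrays else np.empty((0, 3))
    for ci, chain in enumerate(chains):
        core = {p: np.asarray(x, dtype=float)
                for p, x in (chain.core_coords or {}).items()}
        chain_coords: dict[int, np.ndarray] = dict(core)
        for a, b in chain.disordered_runs():
            n_new = b - a + 1
            if not core:                       # fully free chain
                anchor, anchor_prev = None, None
                forward = True
            elif a == 1:                       # N-terminal run, grow backwards
                first_core = min(core)
                anchor = core[first_core]
                anchor_prev = core.get(first_core + 1)
                forward = False
            else:                              # C-terminal run
                last_core = max(core)
                anchor = core[last_core]
                anchor_prev = core.get(last_core - 1)
                forward = True
            new = _grow_segment(rng, anchor, anchor_prev, n_new,
                                existing, clash, max_retries)
            if new is None:
                return None
            # beads leave the anchor in growth order; N-terminal runs are
            # grown outward, so assign positions walking away from the core
            positions = range(a, b + 1) if forward else range(b, a - 1, -1)
            for pos, bead in zip(positions, new):
                chain_coords[pos] = np.asarray(bead)
            existing = np.vstack([existing, np.asarray(new)])
        for pos in range(1, chain.length + 1):
            coords.append(chain_coords[pos])
            rids.append(pos)
            cids.append(ci)
            labels.append("core" if pos in core else "disordered")
    return ConformerModel(
        coords=np.array(coords), residue_ids=np.array(rids),
        chain_ids=np.array(cids), segment_labels=np.array(labels),
    )


def build_pool(chains: Sequence[ChainSpec] | ChainSpec, n_conformers: int,
               seed: int, q_grid: np.ndarray | None = None,
               clash: float = CLASH_DISTANCE, max_retries: int = 500,
               max_failure_fraction: float = 0.1) -> EnsemblePool:
    """Generate a reproducible pool of self-avoiding conformers.

    Each conformer appends coil-sampled C-alpha chains to the rigid core (or
    grows free chains); consecutive beads sit 3.8 A apart and non-adjacent
    beads are kept beyond the clash distance by rejection sampling.  The
    pool is a pure function of (chains, n_conformers, seed).
    """
    if isinstance(chains, ChainSpec):
        chains = [chains]
    if n_conformers < 1:
        raise EnsembleError("n_conformers must be >= 1")
    rng = np.random.default_rng(seed)
    conformers: list[ConformerModel] = []
    failures = 0
    while len(conformers) < n_conformers:
        c = build_conformer(chains, rng, clash=clash, max_retries=max_retries)
        if c is None:
            failures += 1
            if failures > max(10, max_failure_fraction * n_conformers * 10):
                raise EnsembleError(
                    f"chain building failed {failures} times; the core "
                    "geometry may leave no room for the disordered segments")
            continue
        conformers.append(c)
    if failures > max_failure_fraction * n_conformers:
        warnings.warn(f"{failures} conformer restarts during pool building")
    if q_grid is None:
        q_grid = np.linspace(0.01, 0.3, 60)
    q_grid = np.asarray(q_grid, dtype=float)
    profiles = np.array([debye_profile(c, q_grid).i for c in conformers])
    return EnsemblePool(conformers=conformers, q_grid=q_grid,
                        profiles=profiles, seed=seed, n_failures=failures)


# ---------------------------------------------------------------------------
# Debye profiles


def dummy_residue_form_factor(q: np.ndarray,
                              rg_dummy: float = DUMMY_RESIDUE_RG) -> np.ndarray:
    """Gaussian-sphere amplitude for one dummy residue, f(0) = 1."""
    return np.exp(-(np.asarray(q, float) ** 2) * rg_dummy ** 2 / 6.0)


def debye_profile(model: ConformerModel, q_grid: np.ndarray,
                  rg_dummy: float = DUMMY_RESIDUE_RG,
                  histogram_dr: float | None = None) -> ScatteringCurve:
    """Debye double-sum profile of a bead model.

    I(q) = f(q)^2 [N + 2 sum_{i<j} sin(q r_ij)/(q r_ij)] with one Gaussian
    dummy-residue form factor per bead.  The q -> 0 limit is exact
    (I(0) = N^2).  For very large models a distance-histogram approximation
    (bin width ``histogram_dr``) can be enabled; the default is the exact
    sum whenever n_pairs * n_q is affordable, else a 0.5 A histogram.
    """
    q = np.asarray(q_grid, dtype=float)
    f2 = dummy_residue_form_factor(q, rg_dummy) ** 2
    n = model.n_beads
    if n == 1:
        i = f2.copy()
        sigma = np.maximum(1e-6 * np.max(i), 1e-12) * np.ones_like(i)
        return ScatteringCurve(q, i, sigma, metadata={"n_beads": 1})
    d = pdist(model.coords)
    if histogram_dr is None and d.size * q.size > 5e7:
        histogram_dr = 0.5
    if histogram_dr:
        nbins = max(int(np.ceil(d.max() / histogram_dr)), 1)
        hist, edges = np.histogram(d, bins=nbins, range=(0.0, nbins * histogram_dr))
        centers = 0.5 * (edges[:-1] + edges[1:])
        qr = np.outer(q, centers)
        sinc = np.ones_like(qr)
        nz = qr != 0
        sinc[nz] = np.sin(qr[nz]) / qr[nz]
        pair_sum = sinc @ hist
    else:
        qr = np.outer(q, d)
        sinc = np.ones_like(qr)
        nz = qr != 0
        sinc[nz] = np.sin(qr[nz]) / qr[nz]
        pair_sum = sinc.sum(axis=1)
    i = f2 * (n + 2.0 * pair_sum)
    sigma = np.maximum(1e-6 * np.max(np.abs(i)), 1e-12) * np.ones_like(i)
    return ScatteringCurve(q, i, sigma, metadata={"n_beads": n})


# ---------------------------------------------------------------------------
# genetic-algorithm selection


@dataclass(frozen=True)
class EnsembleSelection:
    """Pooled GA output: member weights and the fit quality per run."""

    member_indices: np.ndarray       # unique pool indices
    weights: np.ndarray              # sum to 1
    reduced_chi2: float              # best run
    chi2_per_run: np.ndarray
    rg_distribution: np.ndarray      # weight-expanded (one entry per draw)
    dmax_distribution: np.ndarray
    n_runs: int
    ensemble_size: int
    zero_diversity: bool = False

    def summary(self) -> str:
        return (
            f"GA ensemble selection: {self.n_runs} runs x size "
            f"{self.ensemble_size}\n"
            f"  best reduced chi^2 = {self.reduced_chi2:.3f} "
            f"(median {np.median(self.chi2_per_run):.3f})\n"
            f"  {len(self.member_indices)} distinct members\n"
            f"  selected Rg mean {self.rg_distribution.mean():.2f} A, "
            f"sd {self.rg_distribution.std():.2f} A"
        )


def _optimal_scale(i_model: np.ndarray, i_data: np.ndarray,
                   sigma: np.ndarray, fit_constant: bool) -> tuple[float, float]:
    w = 1.0 / sigma ** 2
    if not fit_constant:
        denom = np.sum(w * i_model ** 2)
        if denom == 0:
            return 0.0, 0.0
        return float(np.sum(w * i_model * i_data) / denom), 0.0
    A = np.column_stack([i_model, np.ones_like(i_model)]) * np.sqrt(w)[:, None]
    b = i_data * np.sqrt(w)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return float(sol[0]), float(sol[1])


def _reduced_chi2(i_model, i_data, sigma, fit_constant):
    c, k = _optimal_scale(i_model, i_data, sigma, fit_constant)
    resid = (c * i_model + k - i_data) / sigma
    dof = max(i_data.size - (2 if fit_constant else 1), 1)
    return float(np.sum(resid ** 2) / dof)


class EnsembleOptimizer:
    """GA search for fixed-size sub-ensembles fitting a target curve.

    Chromosomes are index multisets of size ``ensemble_size`` (repetition
    acts as weighting).  Fitness is the reduced chi^2 of the equal-weight
    ensemble-average profile after an optimal scale (and optional constant)
    fit to the target.  The GA uses elitism, uniform crossover and per-gene
    mutation; ``n_runs`` independent runs from distinct sub-seeds are pooled
    into the final member-weight distribution.
    """

    def __init__(self, pool: EnsemblePool, target: ScatteringCurve,
                 ensemble_size: int = 20, n_generations: int = 200,
                 n_runs: int = 50, population: int = 50,
                 mutation_rate: float = 0.1, crossover_rate: float = 0.5,
                 elitism: int = 1, fit_constant: bool = False,
                 seed: int = 0):
        if ensemble_size > len(pool):
            raise EnsembleError("ensemble_size exceeds pool size")
        if np.any(target.sigma <= 0):
            raise EnsembleError("target curve has degenerate uncertainties")
        if (target.q[0] < pool.q_grid[0] - 1e-12
                or target.q[-1] > pool.q_grid[-1] + 1e-12):
            raise EnsembleError("target q-range outside pool profile grid")
        self.pool = pool
        self.target = target
        self.ensemble_size = ensemble_size
        self.n_generations = n_generations
        self.n_runs = n_runs
        self.population = population
        self.mutation_rate = mutation_rate
        self.crossover_rate = crossover_rate
        self.elitism = elitism
        self.fit_constant = fit_constant
        self.seed = seed
        # interpolate pool profiles onto the target grid once
        self._profiles = np.array([
            np.interp(target.q, pool.q_grid, prof) for prof in pool.profiles
        ])
        # best single conformer, used to seed one chromosome per run
        singles = np.array([
            _reduced_chi2(p, target.i, target.sigma, fit_constant)
            for p in self._profiles
        ])
        self._best_single_idx = int(np.argmin(singles))

    def _fitness(self, chrom: np.ndarray) -> float:
        i_model = self._profiles[chrom].mean(axis=0)
        return _reduced_chi2(i_model, self.target.i, self.target.sigma,
                             self.fit_constant)

    def _run(self, rng: np.random.Generator) -> tuple[np.ndarray, float]:
        n_pool = len(self.pool)
        pop = rng.integers(0, n_pool, size=(self.population, self.ensemble_size))
        pop[0, :] = self._best_single_idx
        fit = np.array([self._fitness(c) for c in pop])
        for _gen in range(self.n_generations):
            order = np.argsort(fit)
            pop, fit = pop[order], fit[order]
            new_pop = [pop[k].copy() for k in range(self.elitism)]
            while len(new_pop) < self.population:
                # tournament selection from the current population
                a, b = rng.integers(0, self.population, 2)
                p1 = pop[min(a, b)]
                a, b = rng.integers(0, self.population, 2)
                p2 = pop[min(a, b)]
                child = p1.copy()
                if rng.random() < self.crossover_rate:
                    mask = rng.random(self.ensemble_size) < 0.5
                    child[mask] = p2[mask]
                mut = np.flatnonzero(rng.random(self.ensemble_size)
                                     < self.mutation_rate)
                for g in mut:
                    # half the mutations draw fresh pool members, half
                    # duplicate another gene of the same chromosome so the
                    # GA can concentrate weight (repetition-as-weight)
                    if rng.random() < 0.5:
                        child[g] = rng.integers(0, n_pool)
                    else:
                        child[g] = child[rng.integers(0, self.ensemble_size)]
                new_pop.append(child)
            pop = np.array(new_pop)
            fit = np.array([self._fitness(c) for c in pop])
        best = int(np.argmin(fit))
        return self._polish(pop[best])

    def _polish(self, chrom: np.ndarray,
                max_sweeps: int = 10) -> tuple[np.ndarray, float]:
        """Greedy single-gene exchanges to the nearest local optimum.

        Replacing gene g by pool member j shifts the ensemble average by
        (profile_j - profile_g)/m, so all candidate chi^2 values for one
        gene are evaluated in a single vectorized pass.
        """
        chrom = chrom.copy()
        m = self.ensemble_size
        w = 1.0 / self.target.sigma ** 2
        i_data = self.target.i
        dof = max(i_data.size - (2 if self.fit_constant else 1), 1)
        current = self._fitness(chrom)
        for _sweep in range(max_sweeps):
            improved = False
            for g in range(m):
                i_avg = self._profiles[chrom].mean(axis=0)
                base = i_avg - self._profiles[chrom[g]] / m
                cand = base[None, :] + self._profiles / m   # (n_pool, n_q)
                if self.fit_constant:
                    chis = np.array([
                        _reduced_chi2(c, i_data, self.target.sigma, True)
                        for c in cand
                    ])
                else:
                    swc = np.sum(w * cand * i_data[None, :], axis=1)
                    sww = np.sum(w * cand ** 2, axis=1)
                    scale = np.where(sww > 0, swc / sww, 0.0)
                    resid2 = (np.sum(w * i_data ** 2)
                              - 2 * scale * swc + scale ** 2 * sww)
                    chis = resid2 / dof
                j = int(np.argmin(chis))
                if chis[j] < current - 1e-12:
                    chrom[g] = j
                    current = float(chis[j])
                    improved = True
            if not improved:
                break
        return chrom, float(current)

    def fit(self) -> EnsembleSelection:
        root = np.random.default_rng(self.seed)
        sub_seeds = root.integers(0, 2 ** 31 - 1, size=self.n_runs)
        all_members, chi2s = [], []
        for s in sub_seeds:
            chrom, chi2 = self._run(np.random.default_rng(int(s)))
            all_members.append(chrom)
            chi2s.append(chi2)
        members = np.concatenate(all_members)
        uniq, counts = np.unique(members, return_counts=True)
        weights = counts / counts.sum()
        rgs = self.pool.rg_distribution
        dmaxs = self.pool.dmax_distribution
        zero_div = bool(np.ptp(rgs) == 0.0)
        return EnsembleSelection(
            member_indices=uniq, weights=weights,
            reduced_chi2=float(np.min(chi2s)),
            chi2_per_run=np.array(chi2s),
            rg_distribution=rgs[members],
            dmax_distribution=dmaxs[members],
            n_runs=self.n_runs, ensemble_size=self.ensemble_size,
            zero_diversity=zero_div,
        )


def gajoe_select(pool: EnsemblePool, target: ScatteringCurve,
                 ensemble_size: int = 20, n_generations: int = 200,
                 n_runs: int = 50, seed: int = 0,
                 **kwargs) -> EnsembleSelection:
    """Functional wrapper around :class:`EnsembleOptimizer`."""
    return EnsembleOptimizer(pool, target, ensemble_size=ensemble_size,
                             n_generations=n_generations, n_runs=n_runs,
                             seed=seed, **kwargs).fit()


def _best_single(pool: EnsemblePool, target: ScatteringCurve,
                 fit_constant: bool = False) -> EnsembleSelection:
    """Exhaustive best single-conformer fit (ensemble size 1)."""
    profiles = np.array([
        np.interp(target.q, pool.q_grid, prof) for prof in pool.profiles
    ])
    chis = np.array([
        _reduced_chi2(p, target.i, target.sigma, fit_constant)
        for p in profiles
    ])
    best = int(np.argmin(chis))
    rgs = pool.rg_distribution
    return EnsembleSelection(
        member_indices=np.array([best]), weights=np.array([1.0]),
        reduced_chi2=float(chis[best]), chi2_per_run=np.array([chis[best]]),
        rg_distribution=np.array([rgs[best]]),
        dmax_distribution=np.array([pool.dmax_distribution[best]]),
        n_runs=1, ensemble_size=1,
        zero_diversity=bool(np.ptp(rgs) == 0.0),
    )


def _best_pair(pool: EnsemblePool, target: ScatteringCurve) -> EnsembleSelection:
    """Exact best equal-weight pair via the weighted Gram matrix."""
    profiles = np.array([
        np.interp(target.q, pool.q_grid, prof) for prof in pool.profiles
    ])
    w = 1.0 / target.sigma ** 2
    d = target.i
    Pw = profiles * w[None, :]
    A = Pw @ d                      # sum w p_i d
    G = Pw @ profiles.T             # sum w p_i p_j
    swd2 = float(np.sum(w * d ** 2))
    num = 0.5 * (A[:, None] + A[None, :])
    den = 0.25 * (np.diag(G)[:, None] + 2.0 * G + np.diag(G)[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        rss = swd2 - np.where(den > 0, num ** 2 / den, 0.0)
    dof = max(d.size - 1, 1)
    chi2 = rss / dof
    a, b = np.unravel_index(int(np.argmin(chi2)), chi2.shape)
    members = np.array(sorted((int(a), int(b))))
    uniq, counts = np.unique(members, return_counts=True)
    rgs = pool.rg_distribution
    return EnsembleSelection(
        member_indices=uniq, weights=counts / counts.sum(),
        reduced_chi2=float(chi2[a, b]), chi2_per_run=np.array([chi2[a, b]]),
        rg_distribution=rgs[members],
        dmax_distribution=pool.dmax_distribution[members],
        n_runs=1, ensemble_size=2,
        zero_diversity=bool(np.ptp(rgs) == 0.0),
    )


def select_ensemble_size(pool: EnsemblePool, target: ScatteringCurve,
                         sizes: Sequence[int] = (1, 2, 3, 5, 10, 20),
                         scan_runs: int = 3, n_runs: int = 20,
                         n_generations: int = 150, seed: int = 0,
                         tol_se: float = 1.0,
                         **kwargs) -> EnsembleSelection:
    """Parsimonious ensemble selection: smallest size the data require.

    Ensemble fitting is prone to overfitting -- large multisets can dip below
    the noise floor of the reduced chi^2 by compensating noise, which smears
    the recovered size distribution.  Following the discrepancy/parsimony
    principle, the GA is run over a ladder of ensemble sizes and the
    *smallest* size whose best reduced chi^2 lies within ``tol_se`` standard
    errors (sqrt(2/N)) of the overall best is selected; the final selection
    re-runs the GA at that size with the full ``n_runs``.  A single-state
    target therefore collapses to a single-member ensemble, while genuinely
    polydisperse targets retain the size they need.
    """
    sizes = sorted(set(int(s) for s in sizes))
    if any(s < 1 for s in sizes):
        raise EnsembleError("ensemble sizes must be >= 1")
    fit_constant = kwargs.get("fit_constant", False)
    exact_pair = not fit_constant   # pair enumeration assumes scale-only fit
    scan: dict[int, float] = {}
    for s in sizes:
        if s == 1:
            scan[s] = _best_single(pool, target, fit_constant).reduced_chi2
        elif s == 2 and exact_pair:
            scan[s] = _best_pair(pool, target).reduced_chi2
        else:
            sel = EnsembleOptimizer(
                pool, target, ensemble_size=s, n_generations=n_generations,
                n_runs=scan_runs, seed=seed + s, **kwargs).fit()
            scan[s] = sel.reduced_chi2
    se = np.sqrt(2.0 / len(target.q))
    best_chi2 = min(scan.values())
    chosen = min(s for s in sizes if scan[s] <= best_chi2 + tol_se * se)
    if chosen == 1:
        return _best_single(pool, target, fit_constant)
    if chosen == 2 and exact_pair:
        return _best_pair(pool, target)
    return EnsembleOptimizer(
        pool, target, ensemble_size=chosen, n_generations=n_generations,
        n_runs=n_runs, seed=seed, **kwargs).fit()


# ---------------------------------------------------------------------------
# flexibility metrics


def _fd_bins(values: np.ndarray, min_bins: int = 10) -> np.ndarray:
    """Freedman-Diaconis bin edges over the value range, at least min_bins."""
    values = np.asarray(values, dtype=float)
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        return np.array([lo - 0.5, hi + 0.5])
    iqr = np.subtract(*np.percentile(values, [75, 25]))
    width = 2.0 * iqr / len(values) ** (1.0 / 3.0) if iqr > 0 else 0.0
    n = int(np.ceil((hi - lo) / width)) if width > 0 else min_bins
    n = max(n, min_bins)
    return np.linspace(lo, hi, n + 1)


def _entropy_percent(values: np.ndarray, edges: np.ndarray) -> float:
    hist, _ = np.histogram(values, bins=edges)
    n_bins = len(edges) - 1
    if n_bins < 2 or hist.sum() == 0:
        return 0.0
    p = hist / hist.sum()
    p = p[p > 0]
    return float(100.0 * -(p * np.log(p)).sum() / np.log(n_bins))


@dataclass(frozen=True)
class FlexMetrics:
    geometric_mean_rg_selected: float
    geometric_mean_rg_pool: float
    rflex_selected: float            # percent
    rflex_pool: float                # percent
    rsigma: float
    n_bins: int

    def summary(self) -> str:
        return (
            f"Rg geometric mean: selected {self.geometric_mean_rg_selected:.2f} A"
            f" vs pool {self.geometric_mean_rg_pool:.2f} A\n"
            f"Rflex: selected {self.rflex_selected:.2f}% vs pool "
            f"{self.rflex_pool:.2f}%  ({self.n_bins} bins)\n"
            f"Rsigma = {self.rsigma:.3f}"
        )


def flex_metrics(selection: EnsembleSelection, pool: EnsemblePool,
                 min_bins: int = 10) -> FlexMetrics:
    """Geometric-mean Rg, entropy-based Rflex and the Rsigma width ratio.

    Rflex is 100 x Shannon entropy of the Rg histogram over the uniform
    (maximum) entropy, computed on a shared Freedman-Diaconis binning
    spanning the pool range, so selected and pool values are commensurate.
    """
    sel = np.asarray(selection.rg_distribution, dtype=float)
    pool_rg = pool.rg_distribution
    if sel.size == 0 or pool_rg.size == 0:
        raise EnsembleError("empty distributions")
    edges = _fd_bins(pool_rg, min_bins=min_bins)
    if sel.size == 1 or np.ptp(sel) == 0.0:
        warnings.warn("selection Rg distribution has zero width; Rflex = 0")
        rflex_sel = 0.0
    else:
        rflex_sel = _entropy_percent(sel, edges)
    sd_pool = float(pool_rg.std())
    rsigma = float(sel.std() / sd_pool) if sd_pool > 0 else float("nan")
    return FlexMetrics(
        geometric_mean_rg_selected=float(np.exp(np.mean(np.log(sel)))),
        geometric_mean_rg_pool=float(np.exp(np.mean(np.log(pool_rg)))),
        rflex_selected=rflex_sel,
        rflex_pool=_entropy_percent(pool_rg, edges),
        rsigma=rsigma,
        n_bins=len(edges) - 1,
    )


def compaction_test(selection: EnsembleSelection, pool: EnsemblePool,
                    n_boot: int = 2000, seed: int = 0,
                    alpha: float = 0.025) -> dict:
    """Left-shift test of the selected Rg distribution against the pool.

    The null distribution of the geometric-mean Rg is built by drawing
    random multisets of the same total size from the pool; the one-sided
    bootstrap p-value classifies the selection as compact (significantly
    left-shifted), extended (right-shifted) or indistinguishable.  The
    default ``alpha`` = 0.025 per tail is a conventional two-sided test at
    the 5% level.
    """
    metrics = flex_metrics(selection, pool)
    rng = np.random.default_rng(seed)
    pool_rg = pool.rg_distribution
    n_draw = selection.rg_distribution.size
    draws = rng.choice(pool_rg, size=(n_boot, n_draw), replace=True)
    null_geo = np.exp(np.mean(np.log(draws), axis=1))
    obs = metrics.geometric_mean_rg_selected
    p_left = float((np.sum(null_geo <= obs) + 1) / (n_boot + 1))
    if p_left < alpha:
        label = "compact"
    elif p_left > 1.0 - alpha:
        label = "extended"
    else:
        label = "indistinguishable"
    return {
        "classification": label,
        "p_left": p_left,
        "delta_geometric_mean_rg": obs - metrics.geometric_mean_rg_pool,
        "rsigma": metrics.rsigma,
        "rsigma_below_one": bool(metrics.rsigma < 1.0),
        "metrics": metrics,
    }


# ---------------------------------------------------------------------------
# PDB core input


def read_core_calpha(path, chain_ids: Sequence[str] | None = None
                     ) -> dict[str, dict[int, np.ndarray]]:
    """Extract C-alpha coordinates per chain from a PDB file."""
    out: dict[str, dict[int, np.ndarray]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if line[12:16].strip() != "CA":
                continue
            ch = line[21].strip() or "A"
            if chain_ids is not None and ch not in chain_ids:
                continue
            resid = int(line[22:26])
            xyz = np.array([float(line[30:38]), float(line[38:46]),
                            float(line[46:54])])
            out.setdefault(ch, {})[resid] = xyz
    if not out:
        raise EnsembleError(f"no C-alpha atoms found in {path}")
    return out
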