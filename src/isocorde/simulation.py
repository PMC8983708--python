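"""Synthetic single-cell counts with planted co-expression modules.

No off-the-shelf single-cell simulator plants *feature co-expression across
cell types*, so validation data is built in two stages:

1. a base gamma-Poisson (negative binomial) simulator draws an
   n_features x n_cells count matrix over K cell types: per-feature baseline
   means are gamma-distributed, each (feature, type) pair carries a lognormal
   multiplicative effect, each cell a lognormal library-size factor, and a
   small fraction of features is boosted as high-expression outliers;
2. a re-ranking construction turns base counts into synthetic features with
   known module membership. Within each cell type, base features are ranked
   by mean expression; the top ``top_n`` and bottom ``top_n`` features form a
   high- and a low-expression pool of count vectors (restricted to that
   type's cells). Each of the 15 modules has a binary peak profile over the
   K types (5 modules peak in 1 type, 5 in 2, 5 in 3; no type peaks in more
   than 6 modules). A synthetic feature receives, per cell type, a count
   vector drawn from that type's high pool if the module peaks there and
   from the low pool otherwise. Draws are without replacement until a pool is
   exhausted, then the pool is reshuffled and recycled with a warning.

Because count vectors are permuted between features rather than altered, the
base simulator's per-type library-size structure is preserved. A refinement
step finally drops synthetic features whose cell-level Pearson correlation
with their module's median profile falls below a threshold, keeping only
cleanly co-expressed module members.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .data_model import CountMatrix

DEFAULT_SCHEDULE = (1, 1, 1, 1, 1, 2, 2, 2, 2, 2, 3, 3, 3, 3, 3)


@dataclasses.dataclass
class BaseSimParams:
    """Tunables of the gamma-Poisson base simulator.

    baseline_shape/scale: gamma law of per-feature baseline means (default
    mean 10 molecules); type_effect_sigma: sd of the lognormal per-(feature,
    type) effect driving between-type differences; library_sigma: sd of the
    lognormal per-cell depth factor; dispersion: NB alpha (var = mu +
    alpha mu^2); prop_hge/mean_hge: fraction and fold of high-expression
    outlier features; feature_length: effective length given to every
    feature (1000 nt makes depth normalization reduce to CPM). Sparsity
    arises from the long lower tail of the per-(feature, type) means, not
    from an explicit technical dropout stage (sequencing-protocol noise
    models are out of scope).
    """

    baseline_shape: float = 2.0
    baseline_scale: float = 5.0
    type_effect_sigma: float = 1.5
    library_sigma: float = 0.2
    dispersion: float = 0.3
    prop_hge: float = 0.03
    mean_hge: float = 5.0
    feature_length: float = 1000.0

    def validate(self) -> None:
        for name in (
            "baseline_shape",
            "baseline_scale",
            "dispersion",
            "mean_hge",
            "feature_length",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.prop_hge <= 1:
            raise ValueError("prop_hge must be in [0, 1]")
        if self.type_effect_sigma < 0 or self.library_sigma < 0:
            raise ValueError("sigmas must be non-negative")


def simulate_base(
    n_cells: int = 1000,
    n_types: int = 8,
    n_features: int = 8000,
    params: BaseSimParams | None = None,
    seed: int = 0,
) -> CountMatrix:
    """Gamma-Poisson base counts over K cell types (deterministic per seed).

    Cells are split as evenly as possible across the types. Setting
    ``type_effect_sigma=0`` removes all between-type structure (a pure null).
    """
    if params is None:
        params = BaseSimParams()
    params.validate()
    if n_types < 2 or n_cells < 2 * n_types or n_features < 1:
        raise ValueError("invalid simulation dimensions")
    rng = np.random.default_rng(seed)
    sizes = np.full(n_types, n_cells // n_types)
    sizes[: n_cells % n_types] += 1
    cell_types = np.repeat([f"type{k + 1}" for k in range(n_types)], sizes)
    baseline = rng.gamma(params.baseline_shape, params.baseline_scale, n_features)
    if params.prop_hge > 0:
        hge = rng.random(n_features) < params.prop_hge
        baseline[hge] *= params.mean_hge
    if params.type_effect_sigma > 0:
        effects = rng.lognormal(
            0.0, params.type_effect_sigma, size=(n_features, n_types)
        )
    else:
        effects = np.ones((n_features, n_types))
    library = rng.lognormal(0.0, params.library_sigma, n_cells)
    type_index = np.repeat(np.arange(n_types), sizes)
    mu = baseline[:, None] * effects[:, type_index] * library[None, :]
    shape = 1.0 / params.dispersion
    lam = rng.gamma(shape, mu * params.dispersion)
    counts = rng.poisson(lam).astype(float)
    ids = [f"feat_{i + 1:05d}" for i in range(n_features)]
    return CountMatrix(
        values=counts,
        isoform_ids=ids,
        cell_ids=[f"cell_{j + 1:04d}" for j in range(n_cells)],
        cell_types=cell_types.tolist(),
        gene_of={i: i.replace("feat", "gene") for i in ids},
        length_of={i: params.feature_length for i in ids},
    )


def design_profiles(
    n_modules: int = 15,
    schedule: tuple[int, ...] = DEFAULT_SCHEDULE,
    K: int = 8,
    max_peaks_per_type: int = 6,
) -> np.ndarray:
    """Binary n_modules x K peak-profile matrix.

    ``schedule[m]`` is the number of peaking cell types of module m (default:
    five one-peak, five two-peak, five three-peak modules). Peaks are placed
    greedily on the currently least-loaded types (ties to the lowest index),
    which keeps every per-type peak count at or below ``max_peaks_per_type``;
    an infeasible schedule raises.
    """
    if len(schedule) != n_modules:
        raise ValueError("schedule length must equal n_modules")
    if any(s < 1 or s > K for s in schedule):
        raise ValueError("each module must peak in 1..K types")
    import itertools

    profiles = np.zeros((n_modules, K), dtype=int)
    loads = np.zeros(K, dtype=int)
    used: list[set[int]] = []
    for m, n_peaks in enumerate(schedule):
        candidates = [
            combo
            for combo in itertools.combinations(range(K), n_peaks)
            if set(combo) not in used
            and all(loads[k] < max_peaks_per_type for k in combo)
        ]
        if not candidates:
            raise ValueError(
                "infeasible schedule: no distinct peak set stays within "
                f"{max_peaks_per_type} peaks per type"
            )
        # prefer peak sets sharing at most one type with every earlier
        # module: modules are meant to be distinguishable profiles, and
        # near-subset peak sets would be near-collinear
        distinct = [
            c for c in candidates if all(len(set(c) & u) <= 1 for u in used)
        ]
        pool = distinct or candidates
        chosen = min(pool, key=lambda c: (sum(loads[k] for k in c), c))
        used.append(set(chosen))
        profiles[m, list(chosen)] = 1
        loads[list(chosen)] += 1
    return profiles


class _Pool:
    """A per-type pool of feature indices, drawn without replacement and
    recycled (reshuffled) with a warning when exhausted."""

    def __init__(self, indices: np.ndarray, rng: np.random.Generator, name: str):
        self.rng = rng
        self.name = name
        self.base = np.asarray(indices)
        self.order = rng.permutation(self.base)
        self.pos = 0
        self.recycled = 0

    def draw(self, n: int) -> np.ndarray:
        out = []
        while n > 0:
            avail = len(self.order) - self.pos
            if avail == 0:
                warnings.warn(f"pool {self.name} exhausted; recycling")
                self.order = self.rng.permutation(self.base)
                self.pos = 0
                self.recycled += 1
                avail = len(self.order)
            take = min(n, avail)
            out.append(self.order[self.pos : self.pos + take])
            self.pos += take
            n -= take
        return np.concatenate(out)


@dataclasses.dataclass
class SimulatedDataset:
    """Synthetic counts plus ground truth module labels."""

    matrix: CountMatrix
    modules: dict[str, int]  # synthetic feature id -> module (1-based)
    profiles: np.ndarray  # n_modules x K binary peak matrix
    top_pool_size: int
    per_module: int
    seed: int

    def module_members(self, module: int) -> list[str]:
        return [f for f, m in self.modules.items() if m == module]

    @property
    def n_modules(self) -> int:
        return int(self.profiles.shape[0])

    def truth_labels(self) -> np.ndarray:
        """Module label per matrix row, aligned to row order."""
        return np.array([self.modules[f] for f in self.matrix.isoform_ids])


def build_modules(
    base: CountMatrix,
    profiles: np.ndarray | None = None,
    top_n: int = 1400,
    per_module: int = 200,
    seed: int = 0,
) -> SimulatedDataset:
    """Assemble synthetic module features by cell-type-wise re-ranking.

    See the module docstring for the construction. Requires the base matrix
    to hold at least 2 * top_n features so the high and low pools are
    disjoint.
    """
    if profiles is None:
        profiles = design_profiles(K=base.k_types)
    profiles = np.asarray(profiles)
    n_modules, K = profiles.shape
    if K != base.k_types:
        raise ValueError("profile width must equal the number of cell types")
    if base.n_isoforms < 2 * top_n:
        raise ValueError("base simulation too small for disjoint top/bottom pools")
    rng = np.random.default_rng(seed)
    type_names = base.type_names()
    cols_of = {t: base.cells_of_type(t) for t in type_names}
    pools: dict[tuple[str, str], _Pool] = {}
    for t in type_names:
        means = base.values[:, cols_of[t]].mean(axis=1)
        ranked = np.argsort(-means, kind="stable")
        pools[(t, "top")] = _Pool(ranked[:top_n], rng, f"{t}/top")
        pools[(t, "bottom")] = _Pool(ranked[-top_n:], rng, f"{t}/bottom")

    n_synth = n_modules * per_module
    values = np.zeros((n_synth, base.n_cells))
    ids, modules = [], {}
    row = 0
    type_means = {
        t: base.values[:, cols_of[t]].mean(axis=1) for t in type_names
    }
    for m in range(n_modules):
        picks: dict[str, np.ndarray] = {}
        for k, t in enumerate(type_names):
            side = "top" if profiles[m, k] == 1 else "bottom"
            drawn = pools[(t, side)].draw(per_module)
            # rank-match within the module: the j-th synthetic feature gets
            # the j-th strongest drawn vector in every cell type, so a
            # feature's peak magnitudes are comparable across its peaking
            # types (keeps within-module profiles coherent)
            picks[t] = drawn[np.argsort(-type_means[t][drawn], kind="stable")]
        for j in range(per_module):
            fid = f"synth_m{m + 1:02d}_f{j + 1:03d}"
            ids.append(fid)
            modules[fid] = m + 1
            for t in type_names:
                cols = cols_of[t]
                values[row, cols] = base.values[picks[t][j], cols]
            row += 1
    length = (
        base.length_of[base.isoform_ids[0]] if base.length_of is not None else 1000.0
    )
    matrix = CountMatrix(
        values=values,
        isoform_ids=ids,
        cell_ids=list(base.cell_ids),
        cell_types=list(base.cell_types),
        gene_of={i: i.replace("synth", "gene") for i in ids},
        length_of={i: length for i in ids},
    )
    return SimulatedDataset(
        matrix=matrix,
        modules=modules,
        profiles=profiles,
        top_pool_size=top_n,
        per_module=per_module,
        seed=seed,
    )


def refine_modules(
    dataset: SimulatedDataset, min_corr: float = 0.75
) -> SimulatedDataset:
    """Drop synthetic features poorly correlated with their module profile.

    Per module, the median profile over cells (median across members, per
    cell) is computed once on entry; members with cell-level Pearson
    correlation below ``min_corr`` against it are removed. A module losing
    all members is dropped with a warning.
    """
    keep_rows: list[int] = []
    id_to_row = {f: i for i, f in enumerate(dataset.matrix.isoform_ids)}
    for m in range(1, dataset.n_modules + 1):
        members = dataset.module_members(m)
        if not members:
            continue
        rows = np.array([id_to_row[f] for f in members])
        block = dataset.matrix.values[rows]
        median = np.median(block, axis=0)
        med_c = median - median.mean()
        med_norm = np.linalg.norm(med_c)
        kept = []
        for r in rows:
            x = dataset.matrix.values[r]
            xc = x - x.mean()
            denom = np.linalg.norm(xc) * med_norm
            corr = float(xc @ med_c / denom) if denom > 0 else 0.0
            if corr >= min_corr:
                kept.append(r)
        if not kept:
            warnings.warn(f"module {m} emptied by refinement; dropped")
            continue
        keep_rows.extend(kept)
    keep_rows = sorted(keep_rows)
    matrix = dataset.matrix.subset_isoforms(keep_rows)
    modules = {f: dataset.modules[f] for f in matrix.isoform_ids}
    return SimulatedDataset(
        matrix=matrix,
        modules=modules,
        profiles=dataset.profiles,
        top_pool_size=dataset.top_pool_size,
        per_module=dataset.per_module,
        seed=dataset.seed,
    )


def simulate_dataset(
    n_cells: int = 1000,
    n_types: int = 8,
    n_features: int = 8000,
    n_modules: int = 15,
    schedule: tuple[int, ...] | None = None,
    top_n: int = 1400,
    per_module: int = 200,
    refine_min_corr: float | None = 0.75,
    params: BaseSimParams | None = None,
    seed: int = 0,
) -> SimulatedDataset:
    """End-to-end default construction: base -> modules -> refinement.

    Seeds for the two stochastic stages are derived from ``seed``;
    the whole construction is deterministic per seed.
    """
    base = simulate_base(
        n_cells=n_cells,
        n_types=n_types,
        n_features=n_features,
        params=params,
        seed=seed,
    )
    profiles = design_profiles(
        n_modules=n_modules,
        schedule=schedule if schedule is not None else DEFAULT_SCHEDULE[:n_modules],
        K=n_types,
    )
    dataset = build_modules(
        base, profiles, top_n=top_n, per_module=per_module, seed=seed + 1
    )
    if refine_min_corr is not None:
        dataset = refine_modules(dataset, min_corr=refine_min_corr)
    return dataset
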