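"""Synthetic microbial communities with planted, recoverable structure.

The generator emulates the structure of a two-regime soil survey: two sample
groups (10 "continuous" vs 9 "rotation" samples by default), hundreds of
taxa, planted correlation modules whose sign composition can differ between
groups, multiplicative group shifts in selected taxa, and soil variables tied
to chosen taxa.  Every planted feature is recorded in a :class:`GroundTruth`
so downstream stages (correlation screening, RMT thresholding, module
detection, robustness, cohesion, permutation tests) can be validated against
known structure.

Model: a latent Gaussian copula with a block correlation matrix (modules at
``within_module_rho``, off-blocks at ``between_module_rho``; planted negative
associations are sign-flipped entries, with nearest-PSD eigenvalue-clipping
repair when flips break positive semi-definiteness).  Latent values map
through a log-normal marginal to expected relative abundances, and counts are
drawn multinomially at fixed sequencing depth, optionally through a
Dirichlet-multinomial layer for overdispersion.  Because every consumer of
these tables works on ranks (Spearman) or proportions, any monotone marginal
would do; the log-normal yields realistic dominance structure and zero
inflation at low depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .tables import AbundanceTable, EnvTable

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "generate_community",
    "generate_env_table",
    "continuous_like_config",
    "rotation_like_config",
    "ENV_VARIABLE_UNITS",
]

#: soil physicochemical panel and units (survey convention)
ENV_VARIABLE_UNITS = {
    "pH": "",
    "TOC": "g/kg",
    "SOM": "g/kg",
    "TN": "g/kg",
    "TP": "g/kg",
    "TK": "g/kg",
    "NO3-N": "mg/kg",
    "NH4-N": "mg/kg",
    "AP": "mg/kg",
    "AK": "mg/kg",
}


def _per_group(value, n_groups: int = 2) -> tuple:
    """Broadcast a scalar or pair into one value per group."""
    if np.isscalar(value):
        return tuple([value] * n_groups)
    value = tuple(value)
    if len(value) != n_groups:
        raise ValueError(f"expected scalar or {n_groups}-tuple, got {value!r}")
    return value


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic scenario.

    ``within_module_rho`` and ``positive_edge_prob`` accept either a scalar
    (both groups share the value) or a per-group pair, so group contrasts in
    association density/positivity can be planted directly.
    """

    n_taxa: int = 300
    n_samples_per_group: tuple[int, int] = (10, 9)
    group_names: tuple[str, str] = ("continuous", "rotation")
    n_modules: int = 4
    module_sizes: list[int] = field(default_factory=lambda: [15, 15, 12, 12])
    within_module_rho: float | tuple[float, float] = 0.8
    between_module_rho: float = 0.05
    positive_edge_prob: float | tuple[float, float] = 0.85
    group_effect_taxa: list[int] = field(default_factory=list)
    group_log2_fold_change: float = 0.0
    sequencing_depth: int = 50_000
    dispersion: float = 1.0
    env_linked_taxa: dict[str, list[int]] = field(default_factory=dict)
    env_noise_sd: float = 0.3
    base_log_sd: float = 1.5
    latent_scale: float = 1.0
    psd_repair: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes length must equal n_modules")
        if sum(self.module_sizes) > self.n_taxa:
            raise ValueError("sum of module sizes exceeds n_taxa")
        between = self.between_module_rho
        for w in _per_group(self.within_module_rho):
            if not 0.0 <= between < w < 1.0:
                raise ValueError(
                    "need 0 ≤ between_module_rho < within_module_rho < 1"
                )
        for p in _per_group(self.positive_edge_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("positive_edge_prob must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be ≥ 0")
        if any(i < 0 or i >= self.n_taxa for i in self.group_effect_taxa):
            raise ValueError("group_effect_taxa indices out of range")
        for var, idx in self.env_linked_taxa.items():
            if any(i < 0 or i >= self.n_taxa for i in idx):
                raise ValueError(f"env_linked_taxa for {var!r} out of range")


@dataclass
class GroundTruth:
    """Planted structure of a generated community."""

    module_of: np.ndarray  # −1 for background taxa
    planted_edges: dict[str, list[tuple[int, int, int]]]  # group → (i, j, sign)
    group_effect_taxa: list[int]
    group_log2_fold_change: float
    env_linked_taxa: dict[str, list[int]]

    def within_module_pairs(self) -> list[tuple[int, int]]:
        pairs = []
        for m in sorted(set(self.module_of[self.module_of >= 0])):
            members = np.flatnonzero(self.module_of == m)
            for a in range(members.size):
                for b in range(a + 1, members.size):
                    pairs.append((int(members[a]), int(members[b])))
        return pairs


def _nearest_psd(corr: np.ndarray, min_eig: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clipping repair to the nearest correlation-like PSD matrix."""
    vals, vecs = np.linalg.eigh(corr)
    vals = np.clip(vals, min_eig, None)
    fixed = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return (fixed + fixed.T) / 2.0


def _group_correlation(
    cfg: ScenarioConfig, group: int, rng: np.random.Generator
) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """Block correlation matrix for one group plus the planted edge list."""
    n = cfg.n_taxa
    within = _per_group(cfg.within_module_rho)[group]
    p_pos = _per_group(cfg.positive_edge_prob)[group]
    corr = np.full((n, n), cfg.between_module_rho)
    np.fill_diagonal(corr, 1.0)

    module_of = np.full(n, -1, int)
    start = 0
    for m, size in enumerate(cfg.module_sizes):
        module_of[start : start + size] = m
        start += size
    planted: list[tuple[int, int, int]] = []
    for m in range(cfg.n_modules):
        members = np.flatnonzero(module_of == m)
        for a in range(members.size):
            for b in range(a + 1, members.size):
                i, j = int(members[a]), int(members[b])
                sign = 1 if rng.random() < p_pos else -1
                corr[i, j] = corr[j, i] = sign * within
                planted.append((i, j, sign))

    min_eig = float(np.linalg.eigvalsh(corr).min())
    if min_eig < -1e-8:
        if not cfg.psd_repair:
            raise ValueError(
                "planted sign flips make the latent correlation matrix "
                "non-positive-semi-definite; set psd_repair=True to apply "
                "nearest-PSD eigenvalue clipping"
            )
        warnings.warn(
            f"latent correlation not PSD (min eigenvalue {min_eig:.3g}); "
            "applying nearest-PSD repair",
            stacklevel=3,
        )
        corr = _nearest_psd(corr)
    return corr, planted


def generate_community(cfg: ScenarioConfig) -> tuple[AbundanceTable, GroundTruth]:
    """Draw one abundance table (both groups) plus its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_taxa

    module_of = np.full(n, -1, int)
    start = 0
    for m, size in enumerate(cfg.module_sizes):
        module_of[start : start + size] = m
        start += size

    base_log = rng.normal(0.0, cfg.base_log_sd, size=n)

    sample_ids: list[str] = []
    group_of: dict[str, str] = {}
    columns: list[np.ndarray] = []
    planted_edges: dict[str, list[tuple[int, int, int]]] = {}

    for g, (gname, n_samples) in enumerate(
        zip(cfg.group_names, cfg.n_samples_per_group)
    ):
        corr, planted = _group_correlation(cfg, g, rng)
        planted_edges[gname] = planted
        chol = np.linalg.cholesky(corr + 1e-10 * np.eye(n))
        z = (chol @ rng.standard_normal((n, n_samples))).T  # samples × taxa

        log_expected = base_log[None, :] + cfg.latent_scale * z
        if g == 1 and cfg.group_effect_taxa:
            log_expected[:, cfg.group_effect_taxa] += (
                cfg.group_log2_fold_change * np.log(2.0)
            )
        expected = np.exp(log_expected)
        props = expected / expected.sum(axis=1, keepdims=True)

        for s in range(n_samples):
            p = props[s]
            if cfg.dispersion == 0:
                counts = rng.multinomial(cfg.sequencing_depth, p)
            else:
                conc = p * (cfg.sequencing_depth / cfg.dispersion)
                q = rng.dirichlet(np.clip(conc, 1e-8, None))
                counts = rng.multinomial(cfg.sequencing_depth, q)
            sid = f"{gname[0].upper()}{s + 1}"
            sample_ids.append(sid)
            group_of[sid] = gname
            columns.append(counts.astype(float))

    table = AbundanceTable(
        taxa_ids=[f"zOTU_{i + 1}" for i in range(n)],
        sample_ids=sample_ids,
        counts=np.column_stack(columns),
        group_of=group_of,
    )
    truth = GroundTruth(
        module_of=module_of,
        planted_edges=planted_edges,
        group_effect_taxa=list(cfg.group_effect_taxa),
        group_log2_fold_change=cfg.group_log2_fold_change,
        env_linked_taxa={k: list(v) for k, v in cfg.env_linked_taxa.items()},
    )
    return table, truth


def generate_env_table(cfg: ScenarioConfig, table: AbundanceTable) -> EnvTable:
    """Soil-variable table with planted taxon links.

    Each linked variable is a linear combination of the log relative
    abundances of its linked taxa plus Gaussian noise of sd
    ``cfg.env_noise_sd`` (relative to the combination's sd); unlinked
    variables are pure standard-normal noise.  Deterministic given
    ``cfg.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7919]))
    totals = table.sample_totals()
    rel = table.counts / totals
    log_rel = np.log(rel + 1e-9)  # taxa × samples

    values = np.empty((table.n_samples, len(ENV_VARIABLE_UNITS)))
    for j, var in enumerate(ENV_VARIABLE_UNITS):
        linked = cfg.env_linked_taxa.get(var, [])
        if linked:
            signal = log_rel[linked, :].mean(axis=0)
            sd = signal.std()
            scale = sd if sd > 0 else 1.0
            values[:, j] = (signal - signal.mean()) / scale + (
                cfg.env_noise_sd * rng.standard_normal(table.n_samples)
            )
        else:
            values[:, j] = rng.standard_normal(table.n_samples)
    return EnvTable(
        sample_ids=list(table.sample_ids),
        variable_names=list(ENV_VARIABLE_UNITS),
        values=values,
        units=dict(ENV_VARIABLE_UNITS),
    )


# ---------------------------------------------------------------------------
# Canonical paired scenarios


def continuous_like_config(seed: int = 0, **overrides) -> ScenarioConfig:
    """Monoculture-like arm: sparser modules, weaker positive bias."""
    params = dict(
        n_taxa=150,
        n_samples_per_group=(10, 9),
        n_modules=4,
        module_sizes=[10, 10, 8, 8],
        within_module_rho=0.75,
        positive_edge_prob=0.6,
        seed=seed,
    )
    params.update(overrides)
    return ScenarioConfig(**params)


def rotation_like_config(seed: int = 0, **overrides) -> ScenarioConfig:
    """Rotation-like arm: denser modules, stronger positive bias.

    Differs from :func:`continuous_like_config` only in module density and
    planted positive-association probability.
    """
    params = dict(
        n_taxa=150,
        n_samples_per_group=(10, 9),
        n_modules=4,
        module_sizes=[16, 16, 13, 13],
        within_module_rho=0.85,
        positive_edge_prob=0.95,
        seed=seed,
    )
    params.update(overrides)
    return ScenarioConfig(**params)
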