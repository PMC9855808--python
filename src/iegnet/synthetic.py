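"""Synthetic cohorts with a known ground-truth coactivation network.

Real IEG studies estimate an unknown "true" pattern of regional coactivation
from a handful of animals.  To make network recovery, thresholding and
group-size stability quantifiable, this module generates cohorts whose
inter-regional correlation structure is induced by an explicit binary network:

1. sample a ground-truth graph (:func:`make_ground_truth`);
2. build the target correlation matrix ``I + effect_r * adjacency``,
   repaired to the nearest positive-definite correlation matrix when the raw
   construction is indefinite (:func:`target_correlation_matrix`);
3. draw animals as independent multivariate-Gaussian vectors with that
   correlation, scale/shift to a density-like range and map through a
   non-negativity transform (:func:`simulate_cohort`).

Defaults emulate the shape of a typical study: a cohort of 12 mice scored
over tens of atlas regions, with c-Fos-like non-negative densities.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.correlation_tools import corr_nearest
from statsmodels.tools.sm_exceptions import IterationLimitWarning

from .errors import NumericalError, ValidationError
from .ingest import RegionTable

#: Eigenvalue floor below which I + effect_r*A is treated as indefinite.
_PD_TOL = 1e-8
#: Eigenvalue floor enforced by the nearest-correlation projection.
_PROJ_EIG_FLOOR = 1e-6

# The projection is deterministic in (adjacency, effect_r); memoise it so
# repeated cohort draws from one truth pay for it once.
_TARGET_CACHE: dict = {}
_TARGET_CACHE_MAX = 32


@dataclass(frozen=True)
class GroundTruth:
    """A known binary coactivation structure over ``n_regions`` regions.

    ``effect_r`` is the target pairwise Pearson correlation on true edges,
    strictly inside (-1, 1). ``seed`` records the structure seed so the same
    truth can back many sampled cohorts.
    """

    n_regions: int
    adjacency: np.ndarray = field(repr=False)
    effect_r: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency)
        if adj.shape != (self.n_regions, self.n_regions):
            raise ValidationError(f"adjacency shape {adj.shape} != ({self.n_regions},)*2")
        if not np.array_equal(adj, adj.T):
            raise ValidationError("adjacency must be symmetric")
        if np.any(np.diag(adj) != 0):
            raise ValidationError("adjacency must have an all-zero diagonal")
        if not np.isin(adj, (0, 1)).all():
            raise ValidationError("adjacency entries must be 0 or 1")
        if not -1.0 < self.effect_r < 1.0:
            raise ValidationError(f"effect_r must be in (-1, 1), got {self.effect_r}")
        object.__setattr__(self, "adjacency", adj.astype(np.int8))

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    def edge_index(self) -> np.ndarray:
        """Boolean vector over the C(N,2) upper-triangle pairs: True on edges."""
        iu = np.triu_indices(self.n_regions, 1)
        return self.adjacency[iu] == 1

    def region_labels(self) -> list[str]:
        width = len(str(self.n_regions))
        return [f"R{i + 1:0{width}d}" for i in range(self.n_regions)]

    # -- export --------------------------------------------------------------

    def to_adjacency_csv(self, path) -> None:
        import pandas as pd

        labels = self.region_labels()
        pd.DataFrame(self.adjacency, index=pd.Index(labels, name="region"),
                     columns=labels).to_csv(path)

    def to_edgelist_tsv(self, path) -> None:
        labels = self.region_labels()
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("region_a\tregion_b\n")
            for i, j in itertools.combinations(range(self.n_regions), 2):
                if self.adjacency[i, j]:
                    fh.write(f"{labels[i]}\t{labels[j]}\n")


@dataclass(frozen=True)
class CohortSpec:
    """Sampling conditions for one synthetic cohort.

    Parameters
    ----------
    n_animals : int
        Cohort size; at least 3 (the smallest group size that yields a
        correlation p-value). Default 12, a typical IEG cohort.
    baseline : float or array
        Per-region mean density (arbitrary density units, >= 0). Default 5.
    noise_sd : float or array
        Per-region dispersion (> 0) in the same units. Default 1.
    transform : {"none", "softplus", "exponential"}
        Map from the latent Gaussian scale to non-negative densities.
        ``softplus`` (default) is near-identity at the default baseline while
        guaranteeing positivity; ``none`` leaves Gaussian values (possibly
        negative) untouched, which keeps Pearson calibration exact.
    outlier : (n_outliers, magnitude) or None
        If set, replace that many animals' latent vectors with a random
        direction of length ``magnitude`` (in noise-SD units) — the classic
        single-aberrant-animal failure mode of small-cohort correlations.
    """

    n_animals: int = 12
    baseline: float | np.ndarray = 5.0
    noise_sd: float | np.ndarray = 1.0
    transform: str = "softplus"
    outlier: tuple[int, float] | None = None

    def __post_init__(self) -> None:
        if self.n_animals < 3:
            raise ValidationError(f"n_animals must be >= 3, got {self.n_animals}")
        if np.any(np.asarray(self.baseline) < 0):
            raise ValidationError("baseline must be >= 0")
        if np.any(np.asarray(self.noise_sd) <= 0):
            raise ValidationError("noise_sd must be > 0")
        if self.transform not in ("none", "softplus", "exponential"):
            raise ValidationError(f"unknown transform {self.transform!r}")
        if self.outlier is not None:
            n_out, mag = self.outlier
            if n_out < 0 or n_out > self.n_animals:
                raise ValidationError("outlier count must be in [0, n_animals]")
            if mag < 0:
                raise ValidationError("outlier magnitude must be >= 0")

    def to_json(self) -> str:
        d = {
            "n_animals": self.n_animals,
            "baseline": np.asarray(self.baseline).tolist(),
            "noise_sd": np.asarray(self.noise_sd).tolist(),
            "transform": self.transform,
            "outlier": list(self.outlier) if self.outlier else None,
        }
        return json.dumps(d, indent=2)


def make_ground_truth(n_regions: int, edge_density: float, seed: int,
                      effect_r: float = 0.7) -> GroundTruth:
    """Sample a binary symmetric hollow adjacency with ``round(edge_density *
    C(n_regions, 2))`` edges drawn uniformly without replacement.

    Deterministic for a fixed ``seed``.
    """
    if int(n_regions) != n_regions or n_regions < 2:
        raise ValidationError(f"n_regions must be an integer >= 2, got {n_regions!r}")
    if not 0.0 <= edge_density <= 1.0:
        raise ValidationError(f"edge_density must be in [0, 1], got {edge_density!r}")
    n_regions = int(n_regions)
    pairs = list(itertools.combinations(range(n_regions), 2))
    n_edges = int(round(edge_density * len(pairs)))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pairs), size=n_edges, replace=False)
    adj = np.zeros((n_regions, n_regions), dtype=np.int8)
    for k in chosen:
        i, j = pairs[k]
        adj[i, j] = adj[j, i] = 1
    return GroundTruth(n_regions=n_regions, adjacency=adj, effect_r=effect_r, seed=seed)


def make_clique_ground_truth(n_regions: int, clique_size: int,
                             effect_r: float = 0.7) -> GroundTruth:
    """Modular ground truth: disjoint cliques of ``clique_size`` regions
    (any remainder left isolated).

    A disjoint-clique adjacency gives ``I + effect_r * A`` a block
    compound-symmetry structure with eigenvalues ``1 + (clique_size - 1) *
    effect_r`` and ``1 - effect_r``, so the raw construction is exactly
    positive definite for any effect in (0, 1) and needs no projection:
    off-clique pairs have *exactly* zero population correlation.  This makes
    the clique truth the right substrate for calibration studies (e.g.
    realized false-discovery proportion), where true nulls must really be
    null.
    """
    if clique_size < 2 or clique_size > n_regions:
        raise ValidationError(f"clique_size must be in [2, n_regions], got {clique_size}")
    if not 0 < effect_r < 1:
        raise ValidationError(f"clique construction needs effect_r in (0, 1), got {effect_r}")
    adj = np.zeros((n_regions, n_regions), dtype=np.int8)
    for start in range(0, n_regions - clique_size + 1, clique_size):
        block = slice(start, start + clique_size)
        adj[block, block] = 1
    np.fill_diagonal(adj, 0)
    return GroundTruth(n_regions=n_regions, adjacency=adj, effect_r=effect_r, seed=0)


def target_correlation_matrix(truth: GroundTruth, return_info: bool = False):
    """The population correlation matrix the cohort sampler draws from.

    The raw construction is ``C0 = I + effect_r * adjacency``: exactly
    ``effect_r`` on true edges and 0 elsewhere.  When ``C0`` is positive
    definite it is returned unchanged.  Otherwise the nearest valid
    correlation matrix (alternating-projection, unit diagonal, eigenvalues
    floored at 1e-6) is returned; the repair shrinks on-edge correlations
    and leaks small off-edge correlations, both reported in ``info``.

    Parameters
    ----------
    return_info : bool
        If True, also return a dict with keys ``projected`` (bool),
        ``max_edge_shrinkage`` and ``max_offdiag_leakage``.

    Raises
    ------
    NumericalError
        If the projection cannot reach the eigenvalue floor within the
        iteration cap; the message reports the residual.
    """
    key = (truth.adjacency.tobytes(), truth.n_regions, truth.effect_r)
    if key in _TARGET_CACHE:
        C, info = _TARGET_CACHE[key]
        return (C.copy(), dict(info)) if return_info else C.copy()
    A = truth.adjacency.astype(float)
    n = truth.n_regions
    raw = np.eye(n) + truth.effect_r * A
    info = {"projected": False, "max_edge_shrinkage": 0.0, "max_offdiag_leakage": 0.0}
    eigmin = float(np.linalg.eigvalsh(raw)[0])
    if eigmin > _PD_TOL:
        _cache_target(key, raw, info)
        return (raw, info) if return_info else raw
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", IterationLimitWarning)
        proj = corr_nearest(raw, threshold=_PROJ_EIG_FLOOR, n_fact=1000)
    proj = (proj + proj.T) / 2.0
    np.fill_diagonal(proj, 1.0)
    eigmin_proj = float(np.linalg.eigvalsh(proj)[0])
    if eigmin_proj < 0.1 * _PROJ_EIG_FLOOR:
        raise NumericalError(
            "nearest-correlation projection did not converge: "
            f"min eigenvalue {eigmin_proj:.3e} below floor {_PROJ_EIG_FLOOR:.0e}"
        )
    on = A == 1
    off = (A == 0) & ~np.eye(n, dtype=bool)
    info["projected"] = True
    if on.any():
        info["max_edge_shrinkage"] = float(np.max(np.abs(proj[on] - truth.effect_r)))
    if off.any():
        info["max_offdiag_leakage"] = float(np.max(np.abs(proj[off])))
    _cache_target(key, proj, info)
    return (proj, info) if return_info else proj


def _cache_target(key, C, info) -> None:
    if len(_TARGET_CACHE) >= _TARGET_CACHE_MAX:
        _TARGET_CACHE.pop(next(iter(_TARGET_CACHE)))
    _TARGET_CACHE[key] = (C.copy(), dict(info))


def simulate_cohort(truth: GroundTruth, spec: CohortSpec, seed: int) -> RegionTable:
    """Draw one cohort: ``spec.n_animals`` independent animals whose regional
    densities share the correlation structure of ``truth``.

    Latent vectors are zero-mean multivariate Gaussian with covariance
    :func:`target_correlation_matrix`, scaled by ``noise_sd``, shifted by
    ``baseline``, passed through the configured non-negativity transform,
    and optionally perturbed by outlier injection.  Deterministic for a
    fixed ``seed`` (independent of the structure seed in ``truth``).
    """
    C = target_correlation_matrix(truth)
    n, a = truth.n_regions, spec.n_animals
    rng = np.random.default_rng(seed)
    # Cholesky with a tiny jitter: the projection floors eigenvalues at 1e-6.
    L = np.linalg.cholesky(C + 1e-10 * np.eye(n))
    latent = (L @ rng.standard_normal((n, a)))
    if spec.outlier is not None:
        n_out, mag = spec.outlier
        cols = rng.choice(a, size=n_out, replace=False)
        for c in cols:
            direction = rng.standard_normal(n)
            direction /= np.linalg.norm(direction)
            latent[:, c] = mag * direction
    baseline = np.broadcast_to(np.asarray(spec.baseline, dtype=float), (n,))
    noise_sd = np.broadcast_to(np.asarray(spec.noise_sd, dtype=float), (n,))
    vals = baseline[:, None] + noise_sd[:, None] * latent
    if spec.transform == "softplus":
        vals = np.logaddexp(0.0, vals)
    elif spec.transform == "exponential":
        vals = np.exp(vals)
    labels = truth.region_labels()
    animals = [f"M{j + 1:02d}" for j in range(a)]
    # transform "none" leaves latent Gaussian values, which may be negative.
    return RegionTable(labels, animals, vals, allow_negative=(spec.transform == "none"))
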