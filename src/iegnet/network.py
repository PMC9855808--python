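"""Correlation matrices and thresholded binary networks.

The construction mirrors the standard IEG functional-connectivity workflow:
regional activity density is Pearson-correlated across animals for every
unordered region pair, two-tailed p-values come from the exact t-transform
with ``n - 2`` degrees of freedom, and the correlation matrix is binarized
into a symmetric hollow adjacency by a :class:`ThresholdSpec` combining a
significance level, optional Benjamini–Hochberg FDR control over the
C(N, 2)-pair family, an optional minimum |r|, and a sign policy for
anticorrelations.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .ingest import RegionTable

logger = logging.getLogger(__name__)

SIGN_POLICIES = ("positive_only", "absolute", "signed")


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def pearson_r(x, y) -> float:
    """Product-moment correlation of two equal-length vectors (n >= 3).

    Raises
    ------
    ValidationError
        On length mismatch, fewer than 3 observations, or a constant vector
        (zero variance makes r undefined; see :func:`correlate_table` for the
        whole-table policy).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(f"vectors must be 1-D of equal length, got {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValidationError(f"need at least 3 observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for a constant vector (zero variance)")
    r = float(stats.pearsonr(x, y).statistic)
    return float(np.clip(r, -1.0, 1.0))


def p_two_tailed(r: float, n: int) -> float:
    """Two-tailed p-value of a Pearson coefficient at group size ``n``.

    Uses the exact transform ``t = r * sqrt(n - 2) / sqrt(1 - r**2)``
    referred to Student's t with ``n - 2`` degrees of freedom; returns 0.0
    at |r| = 1.
    """
    if not np.isfinite(r) or abs(r) > 1:
        raise ValidationError(f"r must be in [-1, 1], got {r!r}")
    if n < 3:
        raise ValidationError(f"group size must be >= 3, got {n}")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def bh_fdr(pvalues, q: float) -> np.ndarray:
    """Benjamini–Hochberg step-up over one family of p-values.

    Finds the largest rank ``k`` with ``p_(k) <= k * q / m`` over the sorted
    p-values and retains every p-value ``<= p_(k)``; retains none when no
    rank passes.  Returns a boolean array aligned with the input.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    if not 0 < q <= 1:
        raise ValidationError(f"FDR rate q must be in (0, 1], got {q!r}")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    passing = np.nonzero(sorted_p <= q * np.arange(1, m + 1) / m)[0]
    if passing.size == 0:
        return np.zeros(m, dtype=bool)
    return p <= sorted_p[passing[-1]]


# ---------------------------------------------------------------------------
# whole-table correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    """Pairwise Pearson r and two-tailed p over all region pairs.

    ``r`` has unit diagonal; the diagonal of ``p`` is NaN (self-correlation
    is meaningless).  ``n`` is the number of animals the matrices came from,
    and ``n_constant_regions`` counts zero-variance regions that were handled
    by the r = 0, p = 1 convention.
    """

    regions: list[str]
    r: np.ndarray = field(repr=False)
    p: np.ndarray = field(repr=False)
    n: int = 0
    n_constant_regions: int = 0

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def upper_triangle(self):
        """(pair index arrays, r vector, p vector) over unordered pairs."""
        iu = np.triu_indices(self.n_regions, 1)
        return iu, self.r[iu], self.p[iu]

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        idx = pd.Index(self.regions, name="region")
        return (pd.DataFrame(self.r, index=idx, columns=self.regions),
                pd.DataFrame(self.p, index=idx, columns=self.regions))


def _corr_p_matrices(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorised Pearson r and two-tailed p for a regions × animals matrix.

    Constant (zero-variance) rows follow the degenerate-data convention:
    every pair involving such a region gets r = 0, p = 1, so a constant
    region can never gain edges and the pipeline never aborts mid-cohort.
    Returns (r, p, number of constant regions).
    """
    values = np.asarray(values, dtype=float)
    n_regions, n = values.shape
    sd = values.std(axis=1)
    constant = sd == 0
    n_constant = int(constant.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(values)
    if n_constant:
        r[constant, :] = 0.0
        r[:, constant] = 0.0
    r = np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    r = (r + r.T) / 2.0

    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[np.abs(r) >= 1.0] = 0.0
    if n_constant:
        p[constant, :] = 1.0
        p[:, constant] = 1.0
    p = np.clip(p, 0.0, 1.0)
    p = (p + p.T) / 2.0
    np.fill_diagonal(p, np.nan)
    return r, p, n_constant


def correlate_table(table: RegionTable) -> CorrelationResult:
    """Cross-correlate every unordered region pair across animals.

    Zero-variance regions are tolerated (r = 0, p = 1 against every partner)
    and logged, since degenerate rows do occur in subsampled or synthetic
    cohorts.
    """
    r, p, n_constant = _corr_p_matrices(table.values)
    if n_constant:
        logger.warning("correlate_table: %d constant region(s) assigned r=0, p=1", n_constant)
    return CorrelationResult(regions=list(table.regions), r=r, p=p,
                             n=table.n_animals, n_constant_regions=n_constant)


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdSpec:
    """Binarization rule for a correlation matrix.

    An unordered pair (i, j) becomes an edge iff all configured conditions
    hold: ``p <= alpha``; BH-FDR retention at rate ``fdr_q`` over the
    C(N, 2)-pair family (skipped when ``fdr_q`` is None); ``|r| >= r_min``
    (skipped when None); and the sign condition — ``positive_only`` keeps
    r > 0 (anticorrelations dropped, the field's common practice),
    ``absolute`` keeps either sign, ``signed`` keeps either sign and stores
    the sign on the edge.
    """

    alpha: float = 0.05
    r_min: float | None = None
    fdr_q: float | None = 0.05
    sign_policy: str = "positive_only"

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValidationError(f"alpha must be in (0, 1], got {self.alpha!r}")
        if self.r_min is not None and not 0 <= self.r_min < 1:
            raise ValidationError(f"r_min must be in [0, 1), got {self.r_min!r}")
        if self.fdr_q is not None and not 0 < self.fdr_q <= 1:
            raise ValidationError(f"fdr_q must be in (0, 1], got {self.fdr_q!r}")
        if self.sign_policy not in SIGN_POLICIES:
            raise ValidationError(
                f"sign_policy must be one of {SIGN_POLICIES}, got {self.sign_policy!r}")

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "r_min": self.r_min, "fdr_q": self.fdr_q,
                "sign_policy": self.sign_policy}


def _edge_mask(r_vec: np.ndarray, p_vec: np.ndarray, spec: ThresholdSpec) -> np.ndarray:
    """Apply the full edge rule to upper-triangle r/p vectors."""
    keep = p_vec <= spec.alpha
    if spec.fdr_q is not None:
        keep &= bh_fdr(p_vec, spec.fdr_q)
    if spec.r_min is not None:
        keep &= np.abs(r_vec) >= spec.r_min
    if spec.sign_policy == "positive_only":
        keep &= r_vec > 0
    return keep


@dataclass
class Network:
    """Binary, symmetric, hollow functional-connectivity network.

    ``provenance`` records the ThresholdSpec and a fingerprint of the inputs;
    ``signs`` holds per-edge correlation signs when the threshold used the
    ``signed`` policy.  ``edge_list`` carries (region_a, region_b, r, p,
    sign) for every retained edge.
    """

    regions: list[str]
    adjacency: np.ndarray = field(repr=False)
    provenance: dict = field(default_factory=dict, repr=False)
    signs: np.ndarray | None = field(default=None, repr=False)
    edge_list: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency)
        if adj.shape != (len(self.regions),) * 2:
            raise ValidationError("adjacency shape does not match region count")
        if not np.array_equal(adj, adj.T) or np.any(np.diag(adj) != 0):
            raise ValidationError("adjacency must be symmetric with a zero diagonal")
        if not np.isin(adj, (0, 1)).all():
            raise ValidationError("adjacency entries must be 0 or 1")
        self.adjacency = adj.astype(np.int8)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    def edges(self) -> list[tuple[str, str]]:
        iu = np.triu_indices(self.n_regions, 1)
        on = self.adjacency[iu] == 1
        return [(self.regions[i], self.regions[j])
                for i, j in zip(iu[0][on], iu[1][on])]

    def edge_set(self) -> set[tuple[str, str]]:
        return set(self.edges())

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.regions)
        g.add_edges_from(self.edges())
        return g

    # -- export --------------------------------------------------------------

    def to_adjacency_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.adjacency,
                            index=pd.Index(self.regions, name="region"),
                            columns=self.regions)

    def to_adjacency_csv(self, path) -> None:
        self.to_adjacency_frame().to_csv(path)

    def to_edgelist_tsv(self, path) -> None:
        cols = ["region_a", "region_b", "r", "p", "sign"]
        df = self.edge_list if self.edge_list is not None else pd.DataFrame(columns=cols)
        df.to_csv(path, sep="\t", index=False)

    def to_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)


def binarize(corr: CorrelationResult, spec: ThresholdSpec) -> Network:
    """Threshold a correlation result into a binary Network."""
    n = corr.n_regions
    iu, r_vec, p_vec = corr.upper_triangle()
    keep = _edge_mask(r_vec, p_vec, spec)
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[0][keep], iu[1][keep]] = 1
    adj = adj + adj.T

    signs = None
    if spec.sign_policy == "signed":
        signs = np.zeros((n, n), dtype=np.int8)
        s = np.sign(r_vec[keep]).astype(np.int8)
        signs[iu[0][keep], iu[1][keep]] = s
        signs = signs + signs.T

    edge_list = pd.DataFrame({
        "region_a": [corr.regions[i] for i in iu[0][keep]],
        "region_b": [corr.regions[j] for j in iu[1][keep]],
        "r": r_vec[keep],
        "p": p_vec[keep],
        "sign": np.sign(r_vec[keep]).astype(int),
    })
    prov = {"threshold": spec.to_dict(), "n_animals": corr.n,
            "n_regions": n, "corr_fingerprint": _fingerprint(corr.r)}
    return Network(regions=list(corr.regions), adjacency=adj, provenance=prov,
                   signs=signs, edge_list=edge_list)


def _fingerprint(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr, dtype=float).tobytes()).hexdigest()[:16]
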