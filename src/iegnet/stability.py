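"""Group-size robustness of correlation networks by exhaustive subsampling.

Cross-animal correlation networks from small cohorts are fragile: removing
or adding one animal can flip an edge's significance verdict.  This module
quantifies that fragility the direct way — for every subgroup size k it
recomputes the correlation matrix on *every* combination of k animals, then
reports per edge

* the significance-flip rate relative to the full-cohort verdict
  (false-negative-type flips for edges significant in the full cohort,
  false-positive-type flips for the rest), and
* the variance of the p-value across the C(n, k) same-size subsamples,

plus per-size aggregates, and selects the combination with the median
within-network p-value variance at a requested size for side-by-side network
comparison.

Exhaustive enumeration is the default.  For cohorts where C(n, k) explodes
(n > ~14) a seeded Monte-Carlo mode caps the number of combinations per size.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .ingest import RegionTable
from .network import ThresholdSpec, _corr_p_matrices, _edge_mask, binarize, \
    CorrelationResult

logger = logging.getLogger(__name__)

MIN_SUBGROUP = 3


def enumerate_subsamples(n: int, k: int) -> list[tuple[int, ...]]:
    """All C(n, k) combinations of animal indices, in lexicographic order.

    Sizes below 3 are rejected: a correlation p-value needs at least one
    degree of freedom beyond the two estimated moments.
    """
    if k < MIN_SUBGROUP:
        raise ValidationError(f"subgroup size must be >= {MIN_SUBGROUP}, got {k}")
    if k > n:
        raise ValidationError(f"subgroup size {k} exceeds cohort size {n}")
    return list(itertools.combinations(range(n), k))


@dataclass
class StabilityReport:
    """Outcome of a subsample scan.

    All per-edge arrays are aligned with ``edges`` (the upper-triangle pair
    list of the region set).  ``full_verdict`` is the significance verdict of
    the complete cohort under the scan's ThresholdSpec; flips are counted
    against it.  ``combo_variance[k]`` holds, for every combination of size
    k, the variance of that combination's p-values across edges (the
    within-network p variance used for median-network selection).
    """

    regions: list[str]
    edges: list[tuple[str, str]]
    sizes: list[int]
    spec: ThresholdSpec
    n_animals: int
    full_verdict: np.ndarray = field(repr=False)
    per_edge_flip: dict = field(repr=False)           # size -> (n_edges,) flip fraction
    per_edge_p_variance: dict = field(repr=False)     # size -> (n_edges,) variance of p
    mean_variance_by_size: dict = field(repr=False)   # size -> float
    median_variance_by_size: dict = field(repr=False)  # size -> float
    combo_variance: dict = field(repr=False)          # size -> (C(n,k),) within-network var
    combinations: dict = field(repr=False)            # size -> list of index tuples
    n_constant_events: int = 0
    exhaustive: bool = True

    @property
    def n_networks(self) -> int:
        return int(sum(len(c) for c in self.combinations.values()))

    def edge_index(self, edge: tuple[str, str]) -> int:
        a, b = edge
        try:
            return self.edges.index((a, b))
        except ValueError:
            try:
                return self.edges.index((b, a))
            except ValueError:
                raise ValidationError(f"unknown region pair {edge!r}") from None

    def to_edge_frame(self) -> pd.DataFrame:
        """Tidy (edge, size, flip_rate, p_variance, class) table."""
        rows = []
        for k in self.sizes:
            flips = self.per_edge_flip[k]
            pvars = self.per_edge_p_variance[k]
            for e, (pair, fl, pv) in enumerate(zip(self.edges, flips, pvars)):
                rows.append({
                    "region_a": pair[0], "region_b": pair[1], "size": k,
                    "flip_rate": fl, "p_variance": pv,
                    "class": "false_negative" if self.full_verdict[e] else "false_positive",
                })
        return pd.DataFrame(rows)

    def to_size_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "size": self.sizes,
            "mean_variance": [self.mean_variance_by_size[k] for k in self.sizes],
            "median_variance": [self.median_variance_by_size[k] for k in self.sizes],
            "n_combinations": [len(self.combinations[k]) for k in self.sizes],
        })

    def to_json(self) -> str:
        import json

        return json.dumps({
            "regions": self.regions,
            "sizes": self.sizes,
            "n_animals": self.n_animals,
            "threshold": self.spec.to_dict(),
            "exhaustive": self.exhaustive,
            "n_networks": self.n_networks,
            "n_constant_events": self.n_constant_events,
            "mean_variance_by_size": {str(k): v for k, v in self.mean_variance_by_size.items()},
            "median_variance_by_size": {str(k): v
                                        for k, v in self.median_variance_by_size.items()},
        }, indent=2)


def subsample_scan(table: RegionTable, sizes, spec: ThresholdSpec,
                   max_combinations: int | None = None,
                   seed: int | None = None) -> StabilityReport:
    """Recompute the network on every same-size animal subset.

    Parameters
    ----------
    table : RegionTable
        The full cohort.
    sizes : iterable of int
        Subgroup sizes to scan (each in [3, n_animals]).
    spec : ThresholdSpec
        Significance rule; the BH-FDR family is re-applied within every
        subsample, so each subsample is judged exactly as a cohort of that
        size would be.
    max_combinations : int, optional
        Cap per size; when C(n, k) exceeds it, a seeded uniform subset of
        combinations is scanned instead (Monte-Carlo mode).
    seed : int, optional
        Used only in Monte-Carlo mode.

    Notes
    -----
    Regions that become constant within a subsample follow the r = 0, p = 1
    convention; the total number of such events is tallied on the report.
    """
    sizes = sorted(set(int(k) for k in sizes))
    n = table.n_animals
    for k in sizes:
        if not MIN_SUBGROUP <= k <= n:
            raise ValidationError(f"size {k} outside [{MIN_SUBGROUP}, {n}]")

    values = table.values
    n_regions = table.n_regions
    iu = np.triu_indices(n_regions, 1)
    edges = [(table.regions[i], table.regions[j]) for i, j in zip(*iu)]

    r_full, p_full, n_const_full = _corr_p_matrices(values)
    full_verdict = _edge_mask(r_full[iu], p_full[iu], spec)

    per_edge_flip, per_edge_p_var = {}, {}
    mean_var, median_var, combo_var, combos_by_size = {}, {}, {}, {}
    n_constant_events = n_const_full
    exhaustive = True
    rng = np.random.default_rng(seed)

    for k in sizes:
        combos = enumerate_subsamples(n, k)
        if max_combinations is not None and len(combos) > max_combinations:
            idx = rng.choice(len(combos), size=max_combinations, replace=False)
            combos = [combos[i] for i in sorted(idx)]
            exhaustive = False
            logger.info("size %d: Monte-Carlo mode, %d of %d combinations",
                        k, len(combos), math.comb(n, k))
        m = len(combos)
        p_all = np.empty((m, len(edges)))
        flips = np.zeros(len(edges))
        for row, combo in enumerate(combos):
            r_sub, p_sub, n_const = _corr_p_matrices(values[:, combo])
            n_constant_events += n_const
            pv = p_sub[iu]
            p_all[row] = pv
            verdict = _edge_mask(r_sub[iu], pv, spec)
            flips += verdict != full_verdict
        per_edge_flip[k] = flips / m
        per_edge_p_var[k] = p_all.var(axis=0)
        mean_var[k] = float(per_edge_p_var[k].mean())
        median_var[k] = float(np.median(per_edge_p_var[k]))
        combo_var[k] = p_all.var(axis=1)
        combos_by_size[k] = combos

    if n_constant_events:
        logger.warning("subsample_scan: %d constant-region events handled as r=0, p=1",
                       n_constant_events)

    return StabilityReport(
        regions=list(table.regions), edges=edges, sizes=sizes, spec=spec,
        n_animals=n, full_verdict=full_verdict,
        per_edge_flip=per_edge_flip, per_edge_p_variance=per_edge_p_var,
        mean_variance_by_size=mean_var, median_variance_by_size=median_var,
        combo_variance=combo_var, combinations=combos_by_size,
        n_constant_events=n_constant_events, exhaustive=exhaustive,
    )


def select_median_variance_network(report: StabilityReport, table: RegionTable,
                                   k: int, spec: ThresholdSpec):
    """The subsample of size k whose within-network p-value variance is the
    median across all combinations, rebuilt as a binary network.

    With an even number of combinations the lower median is taken; exact
    ties in variance are broken by lexicographic combination order (logged).
    Returns ``(network, animal_ids)``.
    """
    if k not in report.combinations:
        raise ValidationError(f"size {k} was not analyzed (sizes: {report.sizes})")
    variances = report.combo_variance[k]
    combos = report.combinations[k]
    order = np.lexsort((np.arange(len(combos)), variances))
    median_pos = order[(len(combos) - 1) // 2]
    tied = np.sum(variances == variances[median_pos])
    if tied > 1:
        logger.info("median-variance selection: %d tied combinations at size %d, "
                    "lexicographic tie-break applied", int(tied), k)
    combo = combos[median_pos]
    sub = table.select_animals(combo)
    r, p, _ = _corr_p_matrices(sub.values)
    corr = CorrelationResult(regions=list(sub.regions), r=r, p=p, n=k)
    net = binarize(corr, spec)
    net.provenance["median_variance_combination"] = [table.animals[i] for i in combo]
    net.provenance["combination_p_variance"] = float(variances[median_pos])
    return net, [table.animals[i] for i in combo]


def flip_rate_curves(report: StabilityReport, edge: tuple[str, str]) -> pd.DataFrame:
    """Per-size significance-flip fractions for one region pair.

    The classification column says which failure mode the flips represent:
    ``false_negative`` for an edge significant in the full cohort,
    ``false_positive`` otherwise.
    """
    e = report.edge_index(edge)
    cls = "false_negative" if report.full_verdict[e] else "false_positive"
    return pd.DataFrame({
        "size": report.sizes,
        "flip_rate": [report.per_edge_flip[k][e] for k in report.sizes],
        "class": cls,
    })
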