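"""Model/Results interface over the connectivity pipeline.

:class:`ConnectivityModel` wraps a validated region × animal density table;
``fit`` estimates the pairwise correlation structure and binarizes it under a
threshold rule, returning a :class:`ConnectivityResults` that carries the
correlation matrices, the binary network, graph metrics, a text summary, and
entry points to the group-size stability scan and plotting.

    >>> model = ConnectivityModel.from_csv("densities.csv")
    >>> res = model.fit(alpha=0.05, fdr_q=0.05)
    >>> print(res.summary())
    >>> report = res.stability(sizes=range(3, 12))
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .ingest import RegionTable, load_region_table, restrict_regions
from .network import CorrelationResult, Network, ThresholdSpec, binarize, correlate_table
from .stability import StabilityReport, select_median_variance_network, subsample_scan


class ConnectivityModel:
    """Cross-animal functional-connectivity model for one cohort.

    Parameters
    ----------
    table : RegionTable or pandas.DataFrame
        Regions as rows, animals as columns, non-negative densities.
    """

    def __init__(self, table):
        if isinstance(table, pd.DataFrame):
            table = RegionTable.from_dataframe(table)
        if not isinstance(table, RegionTable):
            raise TypeError("table must be a RegionTable or DataFrame")
        self.table = table

    # -- constructors --------------------------------------------------------

    @classmethod
    def from_csv(cls, path, regions: list[str] | None = None) -> "ConnectivityModel":
        """Load a density CSV; optionally restrict to a documented node set."""
        table = load_region_table(path)
        if regions is not None:
            table = restrict_regions(table, regions)
        return cls(table)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ConnectivityModel":
        return cls(RegionTable.from_dataframe(df))

    # -- estimation ----------------------------------------------------------

    def correlate(self) -> CorrelationResult:
        """Pairwise Pearson r and two-tailed p over all region pairs."""
        return correlate_table(self.table)

    def fit(self, alpha: float = 0.05, fdr_q: float | None = 0.05,
            r_min: float | None = None,
            sign_policy: str = "positive_only") -> "ConnectivityResults":
        """Estimate the correlation structure and threshold it into a binary
        network.  Defaults: α = 0.05 with BH-FDR at q = 0.05 over the
        C(N, 2)-pair family, anticorrelations excluded."""
        spec = ThresholdSpec(alpha=alpha, fdr_q=fdr_q, r_min=r_min, sign_policy=sign_policy)
        corr = self.correlate()
        net = binarize(corr, spec)
        return ConnectivityResults(self, spec, corr, net)

    @property
    def n_regions(self) -> int:
        return self.table.n_regions

    @property
    def n_animals(self) -> int:
        return self.table.n_animals


class ConnectivityResults:
    """Fitted connectivity structure: correlations, network and metrics."""

    def __init__(self, model: ConnectivityModel, spec: ThresholdSpec,
                 corr: CorrelationResult, network: Network):
        self.model = model
        self.spec = spec
        self.corr = corr
        self.network = network
        self._metrics: _metrics.MetricsReport | None = None

    # -- derived quantities ---------------------------------------------------

    @property
    def metrics(self) -> _metrics.MetricsReport:
        """Graph metrics of the thresholded network (computed lazily)."""
        if self._metrics is None:
            self._metrics = _metrics.compute_metrics(self.network)
        return self._metrics

    def small_world(self, n_null: int = 100, null_model: str = "er_matched",
                    seed: int | None = None) -> float:
        """sigma = (C/C_rand)/(L/L_rand) against a random null ensemble."""
        return _metrics.small_world_sigma(self.network, n_null=n_null,
                                          null_model=null_model, seed=seed)

    def stability(self, sizes=None, max_combinations: int | None = None,
                  seed: int | None = None) -> StabilityReport:
        """Exhaustive same-size subsample scan under this fit's threshold."""
        if sizes is None:
            sizes = range(3, self.model.n_animals)
        return subsample_scan(self.model.table, sizes, self.spec,
                              max_combinations=max_combinations, seed=seed)

    def median_variance_network(self, report: StabilityReport, k: int):
        """The size-k subsample network with median within-network p variance."""
        return select_median_variance_network(report, self.model.table, k, self.spec)

    # -- presentation ----------------------------------------------------------

    def summary(self) -> str:
        m = self.metrics
        deg = m.degree
        lines = [
            "Functional connectivity network",
            "=" * 46,
            f"regions (nodes):        {self.network.n_regions}",
            f"animals (group size):   {self.corr.n}",
            f"threshold:              alpha <= {self.spec.alpha}"
            + (f", BH-FDR q = {self.spec.fdr_q}" if self.spec.fdr_q is not None else "")
            + (f", |r| >= {self.spec.r_min}" if self.spec.r_min is not None else "")
            + f", {self.spec.sign_policy}",
            f"edges:                  {self.network.n_edges} "
            f"of {self.network.n_regions * (self.network.n_regions - 1) // 2} pairs",
            "-" * 46,
            f"network density:        {m.density:.4f}",
            f"global efficiency:      {m.global_efficiency:.4f}",
            f"mean clustering:        {m.mean_clustering:.4f}",
            f"char. path length:      {m.char_path_length:.4f} "
            f"(component coverage {m.component_coverage:.2f})",
            f"degree: mean {deg.mean():.2f}, max {deg.max()} "
            f"({self.network.regions[int(np.argmax(deg))]})",
        ]
        if self.corr.n_constant_regions:
            lines.append(f"constant regions:       {self.corr.n_constant_regions} "
                         "(assigned r=0, p=1)")
        return "\n".join(lines)

    def plot_adjacency(self, ax=None, cmap: str = "Greys"):
        """Minimal adjacency-matrix heatmap (regions ordered as in the table)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        ax.imshow(self.network.adjacency, cmap=cmap, interpolation="nearest",
                  vmin=0, vmax=1)
        ax.set_xticks(range(self.network.n_regions))
        ax.set_yticks(range(self.network.n_regions))
        ax.set_xticklabels(self.network.regions, rotation=90, fontsize=5)
        ax.set_yticklabels(self.network.regions, fontsize=5)
        ax.set_title(f"alpha<={self.spec.alpha}, "
                     f"{self.network.n_edges} edges")
        return ax

    def plot_correlation(self, ax=None, cmap: str = "RdBu_r"):
        """Heatmap of the unthresholded correlation matrix."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        im = ax.imshow(self.corr.r, cmap=cmap, vmin=-1, vmax=1, interpolation="nearest")
        ax.figure.colorbar(im, ax=ax, label="Pearson r")
        ax.set_title("correlated activity matrix")
        return ax
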