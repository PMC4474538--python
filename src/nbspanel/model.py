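"""Network-based stratification as a fit/results model pair.

``NetworkStratification`` couples a binary mutation cohort to a gene
interaction network; ``fit(K)`` smooths profiles over the network,
factorizes them with a graph-regularized NMF under consensus subsampling,
and returns a ``StratificationResults`` holding the subtype labels, the
consensus matrix, the cophenetic correlation, the final metagenes, and —
when clinical data are attached — log-rank and Fisher association tests.

    model = NetworkStratification(cohort, network, clinical=clinical_df)
    res = model.fit(K=4, n_reps=100, seed=7)
    print(res.summary())
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clinical_assoc import (
    FisherResult,
    KmCurve,
    LogRankResult,
    fisher_association,
    km_estimate,
    logrank_test,
)
from .config import AnalysisConfig
from .consensus import (
    ConsensusMatrix,
    SubtypeAssignment,
    average_linkage_cluster,
    consensus_matrix,
    cophenetic_coefficient,
    run_replicates,
)
from .data_io import (
    BinaryMutationMatrix,
    GenePanel,
    binarize,
    filter_samples,
    read_clinical,
    read_mutations,
    read_panel,
)
from .graph_nmf import FactorizationResult, NmfConfig, factorize
from .network_ops import (
    GeneNetwork,
    knn_graph,
    laplacian,
    normalize_adjacency,
    read_network,
    top_fraction_edges,
)
from .propagation import PropagationConfig, propagate, quantile_normalize_columns

logger = logging.getLogger(__name__)

__all__ = ["NetworkStratification", "StratificationResults", "RunReport", "run_pipeline", "compare_panels"]


class NetworkStratification:
    """Model object binding mutation profiles, a gene network, and
    (optionally) clinical outcomes.

    Parameters
    ----------
    mutations
        Filtered binary gene x patient matrix (rows may be a panel subset).
    network
        Weighted gene interaction network; propagation always runs over
        the full network gene space — mutation rows are embedded into it,
        genes absent from the network are dropped with a logged count.
    clinical
        Optional table with columns sample_id, time, event and optional
        grade / stage.
    config
        AnalysisConfig; defaults follow the published protocol.
    """

    def __init__(
        self,
        mutations: BinaryMutationMatrix,
        network: GeneNetwork,
        clinical: pd.DataFrame | None = None,
        config: AnalysisConfig | None = None,
    ) -> None:
        self.config = config or AnalysisConfig()
        self.clinical = clinical

        thresholded = (
            top_fraction_edges(network, self.config.top_fraction)
            if self.config.top_fraction < 1.0
            else network
        )
        self.network = thresholded
        self.adjacency = normalize_adjacency(thresholded, self.config.normalization)
        knn_source = thresholded if self.config.knn_from_thresholded else network
        self.knn = knn_graph(knn_source, self.config.knn_k, binary=self.config.knn_binary)
        self.laplacian = laplacian(self.knn)

        self.mutations = self._embed(mutations, network)

    @staticmethod
    def _embed(mutations: BinaryMutationMatrix, network: GeneNetwork) -> BinaryMutationMatrix:
        """Embed matrix rows into the network gene space (zero rows for
        network genes without mutation data)."""
        idx = {g: i for i, g in enumerate(network.genes)}
        values = np.zeros((network.n_genes, mutations.n_samples), dtype=np.int8)
        dropped = 0
        for i, g in enumerate(mutations.genes):
            gi = idx.get(g)
            if gi is None:
                dropped += 1
                continue
            values[gi, :] = mutations.values[i, :]
        if dropped:
            logger.info("dropped %d mutation-matrix genes absent from the network", dropped)
        if not values.any():
            raise ValueError("no mutation-matrix genes overlap the network")
        return BinaryMutationMatrix(
            values=values, genes=list(network.genes), samples=list(mutations.samples)
        )

    @classmethod
    def from_files(
        cls,
        mutations_path: str | Path | list[str | Path],
        network_path: str | Path,
        clinical_path: str | Path | None = None,
        panel_path: str | Path | None = None,
        config: AnalysisConfig | None = None,
    ) -> "NetworkStratification":
        """Build the model from MAF-like, edge-list, panel and clinical
        files.  Multiple mutation files are concatenated before coding
        (combined-cohort behavior)."""
        config = config or AnalysisConfig()
        paths = mutations_path if isinstance(mutations_path, (list, tuple)) else [mutations_path]
        records = []
        for p in paths:
            records.extend(read_mutations(p))
        network = read_network(network_path)
        matrix = binarize(records, network.genes)
        if panel_path is not None:
            panel = read_panel(panel_path)
            matrix = filter_samples(
                matrix, mode="panel", panel=panel, min_panel=config.min_panel_mutations
            )
        else:
            matrix = filter_samples(matrix, mode="full", min_full=config.min_full_mutations)
        clinical = read_clinical(clinical_path) if clinical_path else None
        return cls(matrix, network, clinical=clinical, config=config)

    # ------------------------------------------------------------------
    def smoothed_profiles(self) -> np.ndarray:
        """Propagated (not yet normalized) profile matrix."""
        cfg = PropagationConfig(
            alpha=self.config.alpha,
            tol=self.config.propagation_tol,
            max_iter=self.config.propagation_max_iter,
        )
        return propagate(self.mutations, self.adjacency, cfg)

    def fit(
        self,
        K: int,
        n_reps: int | None = None,
        subsample: float | None = None,
        seed: int | None = None,
    ) -> "StratificationResults":
        """Consensus-cluster the cohort into K subtypes."""
        cfg = self.config
        n_reps = n_reps if n_reps is not None else cfg.n_reps
        subsample = subsample if subsample is not None else cfg.subsample
        seed = seed if seed is not None else cfg.seed
        nmf_cfg = NmfConfig(
            K=K, lam=cfg.lam, tol=cfg.nmf_tol, max_iter=cfg.nmf_max_iter, seed=seed
        )
        prop_cfg = PropagationConfig(
            alpha=cfg.alpha, tol=cfg.propagation_tol, max_iter=cfg.propagation_max_iter
        )

        replicates = run_replicates(
            self.mutations,
            self.adjacency,
            self.knn,
            nmf_cfg,
            prop_cfg=prop_cfg,
            n_reps=n_reps,
            subsample=subsample,
            seed=seed,
        )
        consensus = consensus_matrix(replicates, self.mutations.n_samples)
        labels = average_linkage_cluster(consensus, K)
        ccc = cophenetic_coefficient(consensus)

        # final full-cohort factorization for reporting metagenes
        smoothed = self.smoothed_profiles()
        F = quantile_normalize_columns(smoothed).values
        factorization = factorize(F, self.knn, nmf_cfg)

        label_series = pd.Series(labels, index=self.mutations.samples, name="cluster")
        return StratificationResults(
            model=self,
            K=K,
            labels=label_series,
            consensus=consensus,
            ccc=ccc,
            factorization=factorization,
            n_replicates=n_reps,
            subsample=subsample,
            seed=seed,
        )


@dataclass
class StratificationResults:
    """Fitted stratification: subtype labels and their diagnostics."""

    model: NetworkStratification
    K: int
    labels: pd.Series
    consensus: ConsensusMatrix
    ccc: float
    factorization: FactorizationResult
    n_replicates: int
    subsample: float
    seed: int
    _assoc_cache: dict = field(default_factory=dict, repr=False)

    @property
    def cluster_sizes(self) -> dict[int, int]:
        return {int(k): int(v) for k, v in self.labels.value_counts().sort_index().items()}

    @property
    def assignment(self) -> SubtypeAssignment:
        return SubtypeAssignment(labels=self.labels.to_numpy(), K=self.K, ccc=self.ccc)

    # -------------------------------------------------- clinical tests
    def _merged_clinical(self) -> pd.DataFrame:
        if self.model.clinical is None:
            raise ValueError("no clinical table attached to the model")
        df = self.model.clinical.copy()
        df["sample_id"] = df["sample_id"].astype(str)
        merged = df[df["sample_id"].isin(self.labels.index)].copy()
        dropped = len(self.labels) - len(merged)
        if dropped:
            logger.info("%d stratified samples lack clinical records and are dropped", dropped)
        merged["cluster"] = self.labels.loc[merged["sample_id"]].to_numpy()
        return merged

    def logrank(self) -> LogRankResult:
        """K-sample log-rank test of survival differences among subtypes."""
        if "logrank" not in self._assoc_cache:
            df = self._merged_clinical()
            self._assoc_cache["logrank"] = logrank_test(
                df["time"].to_numpy(), df["event"].to_numpy(), df["cluster"].to_numpy()
            )
        return self._assoc_cache["logrank"]

    def fisher(self, variable: str = "grade") -> FisherResult:
        """Fisher's exact association of subtype with a clinical factor."""
        key = f"fisher:{variable}"
        if key not in self._assoc_cache:
            df = self._merged_clinical()
            if variable not in df.columns:
                raise ValueError(f"clinical table has no column {variable!r}")
            sub = df.dropna(subset=[variable])
            self._assoc_cache[key] = fisher_association(
                sub["cluster"].to_numpy(), sub[variable].to_numpy(), seed=self.seed
            )
        return self._assoc_cache[key]

    def km_curves(self) -> dict[int, KmCurve]:
        """Kaplan-Meier curve per subtype."""
        df = self._merged_clinical()
        return {
            int(c): km_estimate(g["time"].to_numpy(), g["event"].to_numpy())
            for c, g in df.groupby("cluster")
        }

    def km_frame(self) -> pd.DataFrame:
        """All KM curves stacked as (group, time, survival, at_risk)."""
        return pd.concat(
            [curve.to_frame(group=str(c)) for c, curve in sorted(self.km_curves().items())],
            ignore_index=True,
        )

    # -------------------------------------------------------- reporting
    def summary(self) -> str:
        lines = [
            "Network-based stratification results",
            "=" * 44,
            f"clusters (K):            {self.K}",
            f"patients:                {len(self.labels)}",
            f"replicates:              {self.n_replicates} (subsample {self.subsample:.0%})",
            f"cophenetic correlation:  {self.ccc:.4f}",
            "cluster sizes:           "
            + ", ".join(f"{k}: {v}" for k, v in self.cluster_sizes.items()),
        ]
        if self.model.clinical is not None:
            lr = self.logrank()
            lines.append(
                f"log-rank:                chi2={lr.statistic:.3f}, df={lr.df}, p={lr.p_value:.3g}"
            )
            for variable in ("grade", "stage"):
                if variable in self.model.clinical.columns:
                    fr = self.fisher(variable)
                    lines.append(
                        f"Fisher ({variable}):          p={fr.p_value:.3g} [{fr.method}]"
                    )
        return "\n".join(lines)

    def save(self, outdir: str | Path, prefix: str = "run") -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "labels": outdir / f"{prefix}_K{self.K}_labels.tsv",
            "consensus": outdir / f"{prefix}_K{self.K}_consensus.tsv",
        }
        labels_df = pd.DataFrame(
            {"sample_id": self.labels.index, "K": self.K, "cluster": self.labels.to_numpy()}
        )
        labels_df.to_csv(paths["labels"], sep="\t", index=False)
        pd.DataFrame(
            self.consensus.values, index=self.labels.index, columns=self.labels.index
        ).to_csv(paths["consensus"], sep="\t", index_label="sample_id", float_format="%.6g")
        return paths


# ---------------------------------------------------------------------------
# pipeline over (gene set, K) combinations


@dataclass
class RunReport:
    """One record per (gene set, K): ccc, cluster sizes, association p's."""

    records: pd.DataFrame
    provenance: dict

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def run_pipeline(
    mutations: BinaryMutationMatrix,
    network: GeneNetwork,
    panels: dict[str, GenePanel] | None = None,
    clinical: pd.DataFrame | None = None,
    config: AnalysisConfig | None = None,
    include_full: bool = True,
    outdir: str | Path | None = None,
) -> RunReport:
    """Run stratification for every requested gene set and K.

    ``mutations`` is the raw (unfiltered) binary matrix; each gene set
    applies its own outlier filter, so — as in per-panel cohort accounting
    — different gene sets may retain different sample sets.
    """
    config = config or AnalysisConfig()
    panels = panels or {}
    gene_sets: list[tuple[str, GenePanel | None]] = []
    if include_full:
        gene_sets.append(("full", None))
    gene_sets.extend((name, panels[name]) for name in sorted(panels))
    if not gene_sets:
        raise ValueError("nothing to run: no panels and include_full=False")

    rows = []
    for name, panel in gene_sets:
        if panel is None:
            filtered = filter_samples(mutations, "full", min_full=config.min_full_mutations)
        else:
            filtered = filter_samples(
                mutations, "panel", panel=panel, min_panel=config.min_panel_mutations
            )
        model = NetworkStratification(filtered, network, clinical=clinical, config=config)
        for K in config.K_list:
            res = model.fit(K, seed=config.seed)
            row = {
                "panel": name,
                "K": K,
                "n_samples": len(res.labels),
                "ccc": res.ccc,
                "cluster_sizes": ",".join(str(v) for v in res.cluster_sizes.values()),
            }
            if clinical is not None:
                lr = res.logrank()
                row.update(logrank_stat=lr.statistic, logrank_df=lr.df, logrank_p=lr.p_value)
                for variable in ("grade", "stage"):
                    if variable in clinical.columns:
                        row[f"fisher_{variable}_p"] = res.fisher(variable).p_value
            rows.append(row)
            if outdir is not None:
                res.save(outdir, prefix=name)
    report = RunReport(
        records=pd.DataFrame(rows),
        provenance={"config_digest": config.digest(), "seed": config.seed, "version": "0.1.0"},
    )
    if outdir is not None:
        report.to_tsv(Path(outdir) / "report.tsv")
    return report


def compare_panels(report: RunReport) -> pd.DataFrame:
    """Median ccc per gene set across K values, best first (ties by name)."""
    med = (
        report.records.groupby("panel")["ccc"]
        .median()
        .rename("median_ccc")
        .reset_index()
    )
    return med.sort_values(
        ["median_ccc", "panel"], ascending=[False, True], ignore_index=True
    )
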