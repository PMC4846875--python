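"""Compound-profiling model and results objects.

:class:`CompoundProfiler` is built from a per-cell feature table (plus
plate metadata) and owns the pipeline parameters; :meth:`fit` runs
signed-KS Z-scoring against the vehicle control, replicate-reliability
filtering, Z-matrix assembly, PCA and Ward clustering, returning a
:class:`ProfilingResults` with the estimates, diagnostics and plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats as pstats
from .multivariate import (ClusteringResult, PCAModel, pca_reduce,
                           ward_cluster)

__all__ = ["CompoundProfiler", "ProfilingResults"]

_META_COLS = ("batch_id", "compound", "time_min", "replicate", "cell", "well")


class CompoundProfiler:
    """Phenotypic compound-profiling model over a per-cell feature table.

    Parameters
    ----------
    features : DataFrame
        Long per-cell table with metadata columns ``compound``,
        ``time_min``, ``replicate`` (and optionally ``batch_id``,
        ``cell``) plus one column per descriptor.
    control : str
        Name of the vehicle-control "compound" (default "DMSO"); its cells
        define the null distribution of every descriptor.
    n_boot : int
        Bootstrap rounds for the null SD of the signed KS statistic.
    reliability_threshold : float
        Minimum replicate Pearson r for a (descriptor, time) column.
    var_threshold : float
        Fraction of variance the retained principal components must reach.
    cut_mode, k
        Dendrogram flattening rule: "largest_gap" (default) or "fixed_k".
    bootstrap_mode : {"pair", "single"}
        Null comparator, see :func:`phenoks.stats.bootstrap_null_std`.
    seed : int
        Run-level seed; per-(descriptor, time, replicate) substreams are
        derived deterministically, so results do not depend on execution
        order.
    """

    def __init__(self, features: pd.DataFrame, control: str = "DMSO",
                 n_boot: int = 1000, reliability_threshold: float = 0.4,
                 var_threshold: float = 0.95, cut_mode: str = "largest_gap",
                 k: int | None = None, combine: str = "mean",
                 bootstrap_mode: str = "pair", seed: int = 0):
        required = {"compound", "time_min", "replicate"}
        missing = required - set(features.columns)
        if missing:
            raise ValueError(f"feature table lacks columns {sorted(missing)}")
        if control not in set(features["compound"]):
            raise ValueError(f"control {control!r} absent from feature table")
        self.features = features
        self.control = control
        self.n_boot = n_boot
        self.reliability_threshold = reliability_threshold
        self.var_threshold = var_threshold
        self.cut_mode = cut_mode
        self.k = k
        self.combine = combine
        self.bootstrap_mode = bootstrap_mode
        self.seed = seed
        self.descriptors = [c for c in features.columns
                            if c not in _META_COLS]
        if not self.descriptors:
            raise ValueError("no descriptor columns found")

    @classmethod
    def from_dataframe(cls, features: pd.DataFrame, **kwargs) -> "CompoundProfiler":
        return cls(features, **kwargs)

    @classmethod
    def from_panel(cls, panel, **kwargs) -> "CompoundProfiler":
        """Build from a :class:`phenoks.synthetic.SyntheticPanel`."""
        if panel.features is None:
            raise ValueError("panel has no feature table (image mode?)")
        return cls(panel.features, **kwargs)

    # -- fitting ----------------------------------------------------------

    def fit(self) -> "ProfilingResults":
        feats = self.features
        times = sorted(feats["time_min"].unique())
        reps = sorted(feats["replicate"].unique())
        compounds = sorted(c for c in feats["compound"].unique()
                           if c != self.control)

        records = []
        null_rows = []
        excluded = set()
        ctrl_all = feats[feats["compound"] == self.control]
        for t_idx, t in enumerate(times):
            for r_idx, rep in enumerate(reps):
                ctrl_batch = ctrl_all[(ctrl_all["time_min"] == t)
                                      & (ctrl_all["replicate"] == rep)]
                trt_batch = feats[(feats["time_min"] == t)
                                  & (feats["replicate"] == rep)]
                for d_idx, d in enumerate(self.descriptors):
                    ctrl = ctrl_batch[d].dropna().to_numpy(float)
                    if ctrl.size < 2:
                        excluded.add((d, t))
                        continue
                    sub_seed = np.random.SeedSequence(
                        entropy=self.seed, spawn_key=(d_idx, t_idx, r_idx))
                    rng = np.random.default_rng(sub_seed)
                    null = pstats.bootstrap_null_std(
                        ctrl, n_boot=self.n_boot,
                        seed=rng.integers(0, 2**31 - 1),
                        mode=self.bootstrap_mode)
                    null_rows.append({"descriptor": d, "time_min": t,
                                      "replicate": rep, "std": null.std,
                                      "degenerate": null.degenerate})
                    if null.degenerate or not null.std > 0:
                        excluded.add((d, t))
                        continue
                    for compound in compounds:
                        treated = trt_batch.loc[
                            trt_batch["compound"] == compound, d
                        ].dropna().to_numpy(float)
                        if treated.size == 0:
                            excluded.add((d, t))
                            continue
                        z = pstats.signed_ks(treated, ctrl).signed_d / null.std
                        records.append({"compound": compound, "descriptor": d,
                                        "time_min": t, "replicate": rep,
                                        "z": z})
                    # control row: held-out split of the control cells,
                    # null SD rescaled to the half-sample sizes
                    perm = rng.permutation(ctrl.size)
                    half = ctrl.size // 2
                    h1, h2 = ctrl[perm[:half]], ctrl[perm[half:]]
                    factor = np.sqrt((1 / h1.size + 1 / h2.size)
                                     / (2 / ctrl.size))
                    zc = pstats.signed_ks(h1, h2).signed_d / (null.std * factor)
                    records.append({"compound": self.control, "descriptor": d,
                                    "time_min": t, "replicate": rep, "z": zc})

        z_long = pd.DataFrame(records)
        if z_long.empty:
            raise ValueError("no Z-scores could be computed")

        cand = [(d, t) for d in self.descriptors for t in times
                if (d, t) not in excluded]
        z_reps = {}
        for rep in reps:
            sub = z_long[(z_long["replicate"] == rep)
                         & (z_long["compound"] != self.control)]
            z_reps[rep] = pstats.assemble_z_matrix(
                sub, cand, compounds, times, combine="mean")

        if len(reps) >= 2:
            reliability = pstats.reliability_filter(
                z_reps[reps[0]], z_reps[reps[1]],
                threshold=self.reliability_threshold)
            retained = reliability.retained
        else:
            reliability = None
            retained = cand
        if not retained:
            raise ValueError("reliability filter retained no descriptors")

        z_matrix = pstats.assemble_z_matrix(
            z_long, retained, compounds + [self.control], times,
            combine=self.combine)

        pca = pca_reduce(z_matrix, var_threshold=self.var_threshold)
        clustering = ward_cluster(pca.retained_scores, cut_mode=self.cut_mode,
                                  k=self.k)
        null_stds = pd.DataFrame(null_rows)
        return ProfilingResults(
            model=self, z_long=z_long, z_replicates=z_reps,
            reliability=reliability, retained=list(retained),
            excluded=sorted(excluded), z_matrix=z_matrix,
            null_stds=null_stds, pca=pca, clustering=clustering)


@dataclass
class ProfilingResults:
    """Fitted compound-profiling results.

    Attributes
    ----------
    z_matrix : DataFrame
        Compounds (+ control) x (descriptor, time) standardized Z-scores.
    reliability : ReliabilityReport or None
        Replicate-correlation filter report (None with one replicate).
    pca : PCAModel
    clustering : ClusteringResult
        Ward tree over the retained PC scores plus the flat cut.
    """

    model: CompoundProfiler
    z_long: pd.DataFrame
    z_replicates: dict
    reliability: object
    retained: list
    excluded: list
    z_matrix: pd.DataFrame
    null_stds: pd.DataFrame
    pca: PCAModel
    clustering: ClusteringResult

    @property
    def labels(self) -> pd.Series:
        return self.clustering.labels

    @property
    def n_clusters(self) -> int:
        return self.clustering.n_clusters

    def score_against(self, groups: dict) -> float:
        """Adjusted Rand index of the flat clusters vs a ground-truth map."""
        from sklearn.metrics import adjusted_rand_score

        ids = [s for s in self.clustering.sample_ids if s in groups]
        truth = [groups[s] for s in ids]
        pred = [self.labels[s] for s in ids]
        return float(adjusted_rand_score(truth, pred))

    def summary(self) -> str:
        lines = []
        n_cmpd = len(self.z_matrix) - 1
        cum = np.cumsum(self.pca.variance_fractions)
        k = self.pca.n_components_retained
        lines.append("Compound profiling results")
        lines.append("==========================")
        lines.append(f"Samples:               {len(self.z_matrix)} "
                     f"({n_cmpd} compounds + {self.model.control})")
        lines.append(f"Z-matrix columns:      {self.z_matrix.shape[1]} "
                     f"(descriptor x time)")
        if self.reliability is not None:
            n_total = len(self.reliability.table)
            n_kept = int(self.reliability.table["retained"].sum())
            lines.append(
                f"Reliability filter:    {n_kept}/{n_total} columns kept "
                f"(replicate r > {self.model.reliability_threshold})")
        lines.append(f"PCA:                   {k} PCs retained, "
                     f"cumulative variance {cum[k - 1]:.1%} "
                     f"(threshold {self.model.var_threshold:.0%})")
        lines.append(f"Ward clustering:       {self.n_clusters} clusters "
                     f"({self.clustering.cut_rationale} cut)")
        for cl in sorted(self.labels.unique()):
            members = ", ".join(self.labels.index[self.labels == cl])
            lines.append(f"  cluster {cl}: {members}")
        return "\n".join(lines)

    def save(self, out_dir) -> dict:
        """Write the fitted tables as CSV files; returns name -> path."""
        from pathlib import Path

        from .io import write_z_matrix

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {"z_matrix": write_z_matrix(self.z_matrix,
                                            out_dir / "z_matrix.csv")}
        self.pca.loadings.to_csv(out_dir / "pca_loadings.csv")
        self.pca.scores.to_csv(out_dir / "pca_scores.csv")
        paths["pca_loadings"] = out_dir / "pca_loadings.csv"
        paths["pca_scores"] = out_dir / "pca_scores.csv"
        link = pd.DataFrame(self.clustering.linkage,
                            columns=["node_a", "node_b", "height", "size"])
        link.to_csv(out_dir / "linkage.csv", index=False)
        paths["linkage"] = out_dir / "linkage.csv"
        self.labels.rename_axis("sample").to_csv(out_dir / "clusters.csv")
        paths["clusters"] = out_dir / "clusters.csv"
        if self.reliability is not None:
            self.reliability.table.to_csv(out_dir / "reliability.csv")
            paths["reliability"] = out_dir / "reliability.csv"
        return paths

    # -- plotting ---------------------------------------------------------

    def plot_dendrogram(self, ax=None):
        """Ward dendrogram of the compound profiles."""
        import matplotlib.pyplot as plt
        from scipy.cluster import hierarchy

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        hierarchy.dendrogram(self.clustering.linkage,
                             labels=self.clustering.sample_ids, ax=ax,
                             leaf_rotation=90)
        ax.set_ylabel("Ward merge height")
        return ax

    def plot_scores(self, pcs=(1, 2), ax=None):
        """Scatter of samples in a principal-component plane."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        xs = self.pca.scores[f"PC{pcs[0]}"]
        ys = self.pca.scores[f"PC{pcs[1]}"]
        ax.scatter(xs, ys, c=self.labels.reindex(xs.index), cmap="tab10")
        for name in xs.index:
            ax.annotate(name, (xs[name], ys[name]), fontsize=7)
        frac = self.pca.variance_fractions
        ax.set_xlabel(f"PC{pcs[0]} ({frac[pcs[0] - 1]:.0%})")
        ax.set_ylabel(f"PC{pcs[1]} ({frac[pcs[1] - 1]:.0%})")
        return ax
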