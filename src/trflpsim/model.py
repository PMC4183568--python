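"""Predicted-vs-observed community comparison, statsmodels-style.

`TRFLPBiasModel` is built from an aligned pair of abundance matrices — the
bias-free profiles a community template implies in silico, and the profiles
actually measured (or simulated) for the same samples. Its `fit()` runs the
comparison battery: covariance PCA of each set, Mantel permutation tests on
Euclidean-PC and Bray-Curtis distance matrices, and linear regressions of
observed on predicted Margalef and Gini-Simpson diversity. The returned
`TRFLPBiasResults` carries every statistic and renders a `summary()` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .processing import DEFAULT_DRIFT_WINDOW, process_channel
from .stats import (
    MantelResult,
    PCAResult,
    RegressionResult,
    bray_curtis_matrix,
    covariance_pca,
    euclidean_pc_distances,
    linear_regression,
    mantel_test,
    margalef_index,
    simpson_index,
)

__all__ = ["TRFLPBiasModel", "TRFLPBiasResults", "canonical_trf_label"]


def canonical_trf_label(trf_table, enzyme_name: str, trf_bp: float) -> str:
    """Stable label for a predicted complete TRF: ``<genotype>@<size>``.

    When genotypes collide on a length the lexicographically first id is
    used, matching the tie-break of the observed-bin matcher.
    """
    ids = sorted(
        p.genotype_id
        for p in trf_table.for_enzyme(enzyme_name)
        if p.complete_trf_bp == trf_bp
    )
    if not ids:
        raise KeyError(f"no prediction with TRF {trf_bp} under {enzyme_name}")
    return f"{ids[0]}@{trf_bp:g}"


class TRFLPBiasModel:
    """Comparison model for predicted vs observed community profiles.

    Parameters
    ----------
    predicted, observed:
        Samples × TRF relative-abundance matrices with identical sample
        indices (columns may differ: each set is ordinated in its own
        space, as distance structure — not column identity — is compared).
    groups:
        Optional sample → group labels (e.g. template replicate). When
        given, distances and diversity are computed on group means while
        PCA is fitted on individual samples.
    predicted_totals, observed_totals:
        Per-sample total signal (peak area) used as N in Margalef's index;
        defaults to 1000 per sample when absent.
    """

    def __init__(
        self,
        predicted: pd.DataFrame,
        observed: pd.DataFrame,
        groups: pd.Series | None = None,
        predicted_totals: pd.Series | None = None,
        observed_totals: pd.Series | None = None,
    ) -> None:
        if list(predicted.index) != list(observed.index):
            only_p = sorted(set(predicted.index) - set(observed.index))
            only_o = sorted(set(observed.index) - set(predicted.index))
            raise ValueError(
                "sample labels differ between predicted and observed matrices; "
                f"only in predicted: {only_p}; only in observed: {only_o}"
            )
        self.predicted = predicted
        self.observed = observed
        self.groups = (
            pd.Series(predicted.index, index=predicted.index, name="group")
            if groups is None
            else groups.reindex(predicted.index)
        )
        default_n = pd.Series(1000.0, index=predicted.index)
        self.predicted_totals = (
            default_n if predicted_totals is None else predicted_totals.reindex(predicted.index)
        )
        self.observed_totals = (
            default_n if observed_totals is None else observed_totals.reindex(predicted.index)
        )

    # ------------------------------------------------------------------
    @classmethod
    def from_study(
        cls,
        dataset,
        *,
        min_height: float = 100.0,
        min_size: float = 100.0,
        bin_width: float = 2.0,
        noise_threshold: float = 0.05,
        drift_window: tuple[float, float] = DEFAULT_DRIFT_WINDOW,
    ) -> "TRFLPBiasModel":
        """Build the model from a (simulated or loaded) study dataset.

        Observed peak tables are run through the full processing chain per
        enzyme channel; the two channels are then concatenated with weight
        1/2 each into a single community matrix. The predicted matrix is
        assembled the same way from the replicate templates' bias-free
        profiles, so the two sets are directly comparable.
        """
        manifest = dataset.manifest
        sample_ids = manifest["sample_id"].tolist()
        obs_parts, pred_parts = [], []
        obs_totals = pd.Series(0.0, index=sample_ids)
        n_channels = len(dataset.peak_tables)
        for enz_name in dataset.enzymes:
            channel = process_channel(
                dataset.peak_tables[enz_name],
                enz_name,
                dataset.trf_table,
                min_height=min_height,
                min_size=min_size,
                bin_width=bin_width,
                noise_threshold=noise_threshold,
                drift_window=drift_window,
                sample_ids=sample_ids,
            )
            mat = channel.matrix.reindex(sample_ids).fillna(0.0)
            mat.columns = [f"{enz_name}|{c}" for c in mat.columns]
            obs_parts.append(mat / n_channels)
            obs_totals = obs_totals.add(channel.raw_totals, fill_value=0.0)

            rows = {}
            for _, row in manifest.iterrows():
                profile = dataset.predicted_profiles[
                    (row["template"], row["replicate"], enz_name)
                ]
                rows[row["sample_id"]] = {
                    f"{enz_name}|{canonical_trf_label(dataset.trf_table, enz_name, trf)}": a
                    for trf, a in profile.abundance.items()
                }
            pmat = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
            pred_parts.append(pmat.reindex(sample_ids).sort_index(axis=1) / n_channels)
        observed = pd.concat(obs_parts, axis=1)
        predicted = pd.concat(pred_parts, axis=1)
        predicted_totals = pd.Series(
            dataset.config.total_area * n_channels, index=sample_ids
        )
        return cls(
            predicted=predicted,
            observed=observed,
            groups=dataset.group_of(),
            predicted_totals=predicted_totals,
            observed_totals=obs_totals,
        )

    # ------------------------------------------------------------------
    def _diversity(
        self, matrix: pd.DataFrame, totals: pd.Series, variant: str
    ) -> pd.DataFrame:
        rows = {}
        for sid, row in matrix.iterrows():
            rows[sid] = {
                # N: total fluorescence area, rounded to a whole-count scale
                "margalef": margalef_index(row.to_numpy(), total=round(totals[sid])),
                "simpson": simpson_index(row.to_numpy(), variant=variant),
            }
        return pd.DataFrame.from_dict(rows, orient="index")

    def fit(
        self,
        n_perm: int = 10000,
        n_components: int | None = None,
        simpson_variant: str = "gini",
        seed: int | None = None,
    ) -> "TRFLPBiasResults":
        """Run the full comparison battery and return the results object.

        `n_components` limits the PC scores entering the Euclidean distance
        matrices; None (default) uses all components, i.e. distances between
        the mean-centred profiles themselves — the convention of comparing
        "all PC scores". Pass 2 to restrict to the plotted ordination plane.
        """
        rng = np.random.default_rng(seed)
        pca_pred = covariance_pca(self.predicted)
        pca_obs = covariance_pca(self.observed)

        group_order = sorted(self.groups.unique())
        pred_scores = pca_pred.scores.groupby(self.groups).mean().loc[group_order]
        obs_scores = pca_obs.scores.groupby(self.groups).mean().loc[group_order]
        d_pred_eu = euclidean_pc_distances(pred_scores, n_components)
        d_obs_eu = euclidean_pc_distances(obs_scores, n_components)

        pred_mean = self.predicted.groupby(self.groups).mean().loc[group_order]
        obs_mean = self.observed.groupby(self.groups).mean().loc[group_order]
        d_pred_bc = bray_curtis_matrix(pred_mean)
        d_obs_bc = bray_curtis_matrix(obs_mean)

        mantel_eu = mantel_test(d_pred_eu, d_obs_eu, n_perm=n_perm, seed=rng)
        mantel_bc = mantel_test(d_pred_bc, d_obs_bc, n_perm=n_perm, seed=rng)

        div_pred = (
            self._diversity(self.predicted, self.predicted_totals, simpson_variant)
            .groupby(self.groups)
            .mean()
            .loc[group_order]
        )
        div_obs = (
            self._diversity(self.observed, self.observed_totals, simpson_variant)
            .groupby(self.groups)
            .mean()
            .loc[group_order]
        )
        diversity = pd.DataFrame(
            {
                "predicted_margalef": div_pred["margalef"],
                "observed_margalef": div_obs["margalef"],
                "predicted_simpson": div_pred["simpson"],
                "observed_simpson": div_obs["simpson"],
            }
        )
        reg_margalef = linear_regression(
            diversity["predicted_margalef"], diversity["observed_margalef"]
        )
        reg_simpson = linear_regression(
            diversity["predicted_simpson"], diversity["observed_simpson"]
        )
        return TRFLPBiasResults(
            model=self,
            pca_predicted=pca_pred,
            pca_observed=pca_obs,
            distances={
                "euclidean_pc": (d_pred_eu, d_obs_eu),
                "bray_curtis": (d_pred_bc, d_obs_bc),
            },
            mantel_euclidean=mantel_eu,
            mantel_braycurtis=mantel_bc,
            diversity=diversity,
            margalef_regression=reg_margalef,
            simpson_regression=reg_simpson,
            n_components=n_components,
            simpson_variant=simpson_variant,
        )


@dataclass
class TRFLPBiasResults:
    """Fitted predicted-vs-observed comparison.

    Mantel statistics quantify how faithfully the measured fingerprints
    preserve between-community distances; the diversity regressions how
    faithfully they recover within-community richness and evenness.
    """

    model: TRFLPBiasModel
    pca_predicted: PCAResult
    pca_observed: PCAResult
    distances: Mapping[str, tuple[pd.DataFrame, pd.DataFrame]]
    mantel_euclidean: MantelResult
    mantel_braycurtis: MantelResult
    diversity: pd.DataFrame
    margalef_regression: RegressionResult
    simpson_regression: RegressionResult
    n_components: int | None
    simpson_variant: str

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        """JSON-serialisable report of every fitted statistic."""
        def mantel(m: MantelResult) -> dict:
            return {"r": m.r, "p": m.p, "n_perm": m.n_perm}

        def reg(r: RegressionResult) -> dict:
            return {
                "slope": r.slope,
                "intercept": r.intercept,
                "r_squared": r.r_squared,
                "f_statistic": r.f_statistic,
                "df": list(r.df),
                "p": r.p,
                "n": r.n,
            }

        return {
            "n_samples": int(self.model.predicted.shape[0]),
            "n_groups": int(self.diversity.shape[0]),
            "mantel": {
                "euclidean_pc": mantel(self.mantel_euclidean),
                "bray_curtis": mantel(self.mantel_braycurtis),
            },
            "regression": {
                "margalef": reg(self.margalef_regression),
                "simpson": reg(self.simpson_regression),
            },
            "pca_variance_explained_2pc": {
                "predicted": self.pca_predicted.variance_explained(2),
                "observed": self.pca_observed.variance_explained(2),
            },
            "diversity": {
                g: {k: float(v) for k, v in row.items()}
                for g, row in self.diversity.iterrows()
            },
        }

    def to_json(self, path, **extra) -> None:
        payload = self.to_dict()
        payload.update(extra)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    # ------------------------------------------------------------------
    def summary(self) -> str:
        """Human-readable summary table of the comparison."""
        d = self.to_dict()
        lines = [
            "TRFLP predicted-vs-observed comparison",
            "=" * 54,
            f"samples: {d['n_samples']}   groups (template replicates): {d['n_groups']}",
            f"PCA variance explained (PC1+PC2): predicted "
            f"{100 * d['pca_variance_explained_2pc']['predicted']:.0f}%, observed "
            f"{100 * d['pca_variance_explained_2pc']['observed']:.0f}%",
            "",
            "Mantel tests (predicted vs observed distances)",
            "-" * 54,
            f"{'distance':<22}{'r':>8}{'p':>12}{'n_perm':>10}",
        ]
        for name, m in (
            ("Euclidean (PC scores)", self.mantel_euclidean),
            ("Bray-Curtis", self.mantel_braycurtis),
        ):
            p_str = "   --" if m.p is None else f"{m.p:>12.4g}"
            lines.append(f"{name:<22}{m.r:>8.3f}{p_str}{m.n_perm:>10}")
        lines += [
            "",
            "Diversity recovery (observed ~ predicted, OLS)",
            "-" * 54,
            f"{'index':<12}{'slope':>8}{'R2':>8}{'F':>10}{'df':>10}{'p':>12}",
        ]
        for name, r in (
            ("Margalef", self.margalef_regression),
            ("Simpson", self.simpson_regression),
        ):
            lines.append(
                f"{name:<12}{r.slope:>8.3f}{r.r_squared:>8.3f}"
                f"{r.f_statistic:>10.3g}{str(r.df):>10}{r.p:>12.4g}"
            )
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def plot_ordination(self, which: str = "observed", ax=None):
        """Scatter of group-mean PC1/PC2 scores for one profile set."""
        import matplotlib.pyplot as plt

        pca = self.pca_observed if which == "observed" else self.pca_predicted
        scores = pca.scores.groupby(self.model.groups).mean()
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(scores["PC1"], scores["PC2"], s=25)
        for label, row in scores.iterrows():
            ax.annotate(str(label), (row["PC1"], row["PC2"]), fontsize=7)
        ax.set_xlabel(f"PC1 ({100 * pca.explained[0]:.0f}%)")
        ax.set_ylabel(f"PC2 ({100 * pca.explained[1]:.0f}%)")
        ax.set_title(f"{which} profiles, covariance PCA")
        return ax

    def plot_distance_agreement(self, metric: str = "bray_curtis", ax=None):
        """Predicted vs observed pairwise distances for one metric."""
        import matplotlib.pyplot as plt

        d_pred, d_obs = self.distances[metric]
        iu = np.tril_indices(d_pred.shape[0], k=-1)
        x = d_pred.to_numpy()[iu]
        y = d_obs.to_numpy()[iu]
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(x, y, s=12, alpha=0.6)
        lim = max(x.max(), y.max())
        ax.plot([0, lim], [0, lim], lw=0.8, color="grey")
        ax.set_xlabel("predicted distance")
        ax.set_ylabel("observed distance")
        ax.set_title(metric)
        return ax
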