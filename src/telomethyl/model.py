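"""Model/Results interface over the screening-and-selection pipeline.

`MethylomeTelomereModel` is built from an outcome vector, a methylation beta
matrix and a covariate table; `fit()` runs EWAS pre-screening (with
empirical-null correction), adaptive-lasso candidate selection, pairwise
interaction construction, elastic-net stability selection, term expansion
and the final ridge fit with bootstrap inference, and returns a
`MethylomeTelomereResults` carrying the estimates, their bootstrap
p-values, fit statistics and intermediate tables.

The outcome enters the selection stage unadjusted by default, matching the
weighted-sum model form (covariates are used in the EWAS screen only); set
``residualize=True`` to pre-regress the outcome on the covariates first.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .qc import BetaMatrix
from .ewas import run_ewas
from . import selection as sel

__all__ = ["MethylomeTelomereModel", "MethylomeTelomereResults"]

DEFAULT_COVARIATES = [
    "sex", "ethnicity_european", "birth_weight", "gestational_age",
    "maternal_age", "maternal_bmi", "parity", "maternal_education",
    "maternal_smoking", "pregnancy_complications", "paternal_age",
    # one cell fraction dropped: the seven sum to one
    "cell_gran", "cell_mono", "cell_nk", "cell_bcell", "cell_cd4t", "cell_cd8t",
]


class MethylomeTelomereModel:
    """Explanatory model of a telomere outcome from CpG methylation.

    Parameters
    ----------
    endog : array-like
        Outcome per sample (baseline T/S or attrition rate, T/S per year).
    beta : BetaMatrix or DataFrame
        Samples x CpGs methylation levels; must be complete (run QC first).
    covariates : DataFrame, optional
        EWAS adjustment covariates, row-aligned with the beta matrix.
    config : PenalizedFitConfig, optional
        Tuning parameters for the penalized stages.
    """

    def __init__(self, endog, beta, covariates: pd.DataFrame | None = None,
                 config: sel.PenalizedFitConfig | None = None,
                 screen_threshold: float = 0.01, residualize: bool = False):
        if isinstance(beta, BetaMatrix):
            self.beta = beta
        else:
            self.beta = BetaMatrix.from_frame(pd.DataFrame(beta))
        self.endog = np.asarray(endog, float)
        if self.endog.shape[0] != self.beta.n_samples:
            raise ValueError("endog length does not match beta matrix")
        self.covariates = covariates
        self.config = config or sel.PenalizedFitConfig()
        self.screen_threshold = screen_threshold
        self.residualize = residualize

    @classmethod
    def from_cohort(cls, cohort, outcome: str = "baseline_tl",
                    config: sel.PenalizedFitConfig | None = None,
                    **kwargs) -> "MethylomeTelomereModel":
        """Build from a SyntheticCohort for either supported outcome."""
        from .telomere import rtm_corrected_attrition
        if outcome == "baseline_tl":
            y = cohort.telomeres.x1
        elif outcome == "attrition_rate":
            y = rtm_corrected_attrition(cohort.telomeres).rate
        else:
            raise ValueError(f"unknown outcome: {outcome!r}")
        cols = [c for c in DEFAULT_COVARIATES if c in cohort.covariates.columns]
        return cls(y, cohort.beta, covariates=cohort.covariates[cols],
                   config=config, **kwargs)

    def _covariate_matrix(self) -> np.ndarray | None:
        if self.covariates is None:
            return None
        return self.covariates.to_numpy(float)

    def fit(self, seed: int | None = None, compute_bootstrap: bool = True,
            candidates: list[str] | None = None,
            ) -> "MethylomeTelomereResults":
        """Run the full selection chain; ``candidates`` skips the EWAS screen."""
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        C = self._covariate_matrix()
        y = self.endog.copy()
        if self.residualize and C is not None:
            X = np.column_stack([np.ones(len(y)), C])
            y = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]

        if candidates is None:
            ewas_table = run_ewas(y, self.beta, C,
                                  screen_threshold=self.screen_threshold)
            candidates = [str(c) for c in
                          ewas_table.index[ewas_table["candidate"]]]
        else:
            missing = [c for c in candidates if c not in set(self.beta.cpg_ids)]
            if missing:
                raise ValueError(f"unknown candidate CpGs: {missing[:5]}")
            ewas_table = pd.DataFrame(index=pd.Index(candidates, name="cpg"))
        if not candidates:
            raise RuntimeError("EWAS screening produced no candidate CpGs")

        beta_df = self.beta.to_frame()[candidates]
        X_std, means, sds = sel.standardize(beta_df)
        a = sel.adaptive_weights(X_std, y, cfg)
        mains, _ = sel.adaptive_lasso_select(X_std, y, a, cfg)

        if mains:
            inter = sel.build_interactions(X_std, mains)
            X_terms = pd.concat([X_std[mains], inter], axis=1)
            profile = sel.stability_selection(X_terms, y, cfg)
            active = profile.active(cfg.frequency_threshold)
        else:
            profile = sel.StabilityProfile(
                frequency=pd.Series(dtype=float), counts=pd.Series(dtype=int),
                n_subsamples=0, records=pd.DataFrame(
                    columns=["alpha", "lambda_1se", "n_selected"]))
            active = []
        active_mains = [t for t in active if sel.INTERACTION_SEP not in t]
        active_inter = [t for t in active if sel.INTERACTION_SEP in t]
        final_mains, final_inter = sel.expand_terms(active_mains, active_inter)

        cols = {m: X_std[m] for m in final_mains}
        for t in final_inter:
            s, u = sel.split_interaction(t)
            cols[t] = X_std[s] * X_std[u]
        X_final = pd.DataFrame(cols, index=X_std.index)
        if X_final.shape[1] == 0:
            # no stable signal: the model degenerates to the outcome mean
            final = sel.FinalModel(intercept=float(np.mean(y)),
                                   weights=pd.Series(dtype=float), lambda_=0.0,
                                   r_pearson=0.0, r_squared=0.0,
                                   fitted=np.full(len(y), np.mean(y)))
        else:
            final = sel.final_ridge_fit(X_final, y, cfg)
            if compute_bootstrap and cfg.b_bootstrap > 0:
                sel.bootstrap_pvalues(final, X_final, y, cfg.b_bootstrap, cfg.seed)
        return MethylomeTelomereResults(
            model=self, config=cfg, endog_used=y, ewas_table=ewas_table,
            candidates=candidates, adaptive_mains=mains,
            stability=profile, final_mains=final_mains,
            final_interactions=final_inter, final_model=final,
            standardization=(means, sds))


@dataclass
class MethylomeTelomereResults:
    """Fitted selection pipeline: estimates, uncertainty, diagnostics."""

    model: MethylomeTelomereModel
    config: sel.PenalizedFitConfig
    endog_used: np.ndarray
    ewas_table: pd.DataFrame
    candidates: list[str]
    adaptive_mains: list[str]
    stability: sel.StabilityProfile
    final_mains: list[str]
    final_interactions: list[str]
    final_model: sel.FinalModel
    standardization: tuple[pd.Series, pd.Series]

    @property
    def params(self) -> pd.Series:
        return pd.concat([pd.Series({"intercept": self.final_model.intercept}),
                          self.final_model.weights])

    @property
    def bootstrap_pvalues(self) -> pd.Series | None:
        return self.final_model.bootstrap_p

    @property
    def rsquared(self) -> float:
        return self.final_model.r_squared

    @property
    def r_pearson(self) -> float:
        return self.final_model.r_pearson

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.final_model.fitted

    def predict(self, beta_df: pd.DataFrame) -> np.ndarray:
        """Weighted sum on new samples (standardized with training moments)."""
        means, sds = self.standardization
        Z = (beta_df[self.final_mains] - means[self.final_mains]) / sds[self.final_mains]
        yhat = np.full(len(beta_df), self.final_model.intercept)
        for term, w in self.final_model.weights.items():
            if sel.INTERACTION_SEP in term:
                s, t = sel.split_interaction(term)
                yhat = yhat + w * (Z[s] * Z[t]).to_numpy()
            else:
                yhat = yhat + w * Z[term].to_numpy()
        return yhat

    def summary(self) -> str:
        fm = self.final_model
        lines = [
            "Methylome telomere model",
            "=" * 64,
            f"samples: {len(self.endog_used)}    CpGs screened: {len(self.ewas_table)}",
            f"EWAS candidates (corrected p < {self.model.screen_threshold}): "
            f"{len(self.candidates)}",
            f"adaptive-lasso mains: {len(self.adaptive_mains)}    "
            f"stability subsamples: {self.stability.n_subsamples}",
            f"final terms: {len(fm.weights)} "
            f"({len(self.final_mains)} mains + {len(self.final_interactions)} interactions)",
            f"Pearson r = {fm.r_pearson:.3f}    R^2 = {fm.r_squared:.3f}    "
            f"ridge lambda = {fm.lambda_:.4g}",
            "-" * 64,
        ]
        tab = fm.to_frame()
        tab["weight"] = tab["weight"].map("{:+.4f}".format)
        lines.append(tab.to_string(index=False))
        return "\n".join(lines)
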