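"""Random-intercept multilevel models feeding the Bayes-factor engine.

Trial-level outcomes are clustered within participants, so every analysis
model is a Gaussian linear mixed model with a participant random intercept,
fitted by REML (ML behind a flag).  From each fit we extract the
fixed-effect estimates and their covariance (the normal posterior
approximation), the variance components, the intraclass correlation

    ICC = s2_intercept / (s2_intercept + s2_residual),

and the effective sample size of the clustered data

    n_eff = n / (1 + (n_cluster - 1) * ICC),

which lies between the number of participants and the number of
observations and calibrates the fractional prior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .evidence import PosteriorApprox

__all__ = [
    "ModelFit",
    "effective_sample_size",
    "fit_random_intercept_model",
    "cell_means_fit",
    "build_eq2_design",
    "fit_detail_affect_model",
    "ols_fit",
]


@dataclass
class ModelFit:
    """Summary of a fitted random-intercept model."""

    coef: pd.Series
    vcov: pd.DataFrame
    s2_int: float
    s2_res: float
    n: int
    n_participants: int
    n_cluster: float
    converged: bool
    method: str = "reml"

    @property
    def icc(self) -> float:
        tot = self.s2_int + self.s2_res
        return float(self.s2_int / tot) if tot > 0 else 0.0

    @property
    def n_eff(self) -> float:
        return effective_sample_size(self.n, self.n_cluster, self.icc)

    def posterior(self, names: list[str] | None = None) -> PosteriorApprox:
        """Normal posterior approximation on (a subset of) the fixed effects."""
        names = list(self.coef.index) if names is None else list(names)
        sigma = self.vcov.loc[names, names].to_numpy()
        # optimizer round-off can leave tiny asymmetries / negative eigenvalues
        sigma = (sigma + sigma.T) / 2.0
        vals, vecs = np.linalg.eigh(sigma)
        if vals.min() < 0:
            sigma = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
            sigma = (sigma + sigma.T) / 2.0
        return PosteriorApprox(
            gamma_hat=self.coef.loc[names].to_numpy(),
            sigma=sigma,
            n_eff=self.n_eff,
            names=tuple(names),
        )

    def to_dict(self) -> dict:
        return {
            "coef": self.coef.to_dict(),
            "vcov": self.vcov.to_numpy().tolist(),
            "coef_names": list(self.coef.index),
            "s2_int": self.s2_int,
            "s2_res": self.s2_res,
            "icc": self.icc,
            "n": self.n,
            "n_participants": self.n_participants,
            "n_cluster": self.n_cluster,
            "n_eff": self.n_eff,
            "converged": self.converged,
            "method": self.method,
        }


def effective_sample_size(n: float, n_cluster: float, icc: float) -> float:
    """n / (1 + (n_cluster - 1) * ICC): information content of clustered data.

    Equals ``n`` under independence (ICC = 0) and the number of clusters
    under total clustering (ICC = 1, balanced design).
    """
    if n_cluster < 1:
        raise ValueError("n_cluster must be at least 1")
    if not 0.0 <= icc <= 1.0:
        raise ValueError("icc must lie in [0, 1]")
    return float(n / (1.0 + (n_cluster - 1.0) * icc))


def fit_random_intercept_model(
    data: pd.DataFrame,
    outcome: str,
    fixed: str = "1",
    groups: str = "participant",
    reml: bool = True,
) -> ModelFit:
    """Fit ``outcome ~ fixed`` with a participant random intercept.

    ``fixed`` is a patsy right-hand-side (e.g. ``"0 + C(cell)"`` for cell
    means).  Trials with a missing outcome or predictors are dropped
    listwise and cluster sizes recomputed.  Unbalanced designs use the mean
    cluster size in the effective-sample-size formula.
    """
    cols = [outcome, groups]
    df = data.dropna(subset=[c for c in cols if c in data.columns]).copy()
    if df[groups].nunique() < 2:
        raise ValueError("need at least 2 participants (clusters)")
    if np.isclose(df[outcome].std(ddof=0), 0.0):
        raise ValueError(f"outcome {outcome!r} is constant")

    # fit on a unit-SD outcome for optimizer stability, rescale afterwards
    scale = float(df[outcome].std(ddof=1))
    df = df.assign(**{outcome: df[outcome] / scale})
    model = sm.MixedLM.from_formula(
        f"{outcome} ~ {fixed}", groups=df[groups], data=df
    )
    fit = None
    last_err: Exception | None = None
    for method in ("lbfgs", "powell", "cg"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                candidate = model.fit(reml=reml, method=method)
        except (np.linalg.LinAlgError, ValueError) as err:
            last_err = err
            continue
        # an optimizer can report convergence from a degenerate boundary
        # point with an exploded covariance; sanity-check before accepting
        # (outcome is unit-variance here, so cell-mean variances are O(1/n))
        vc = np.asarray(candidate.cov_params())[: len(candidate.fe_params), : len(candidate.fe_params)]
        if candidate.converged and np.all(np.isfinite(vc)) and np.abs(np.diag(vc)).max() < 10.0:
            fit = candidate
            break
    if fit is None or not fit.converged:
        raise RuntimeError(
            f"mixed model for {outcome!r} did not converge "
            f"(fixed='{fixed}', n={len(df)}, last error: {last_err}); "
            "inspect the data or rescale"
        )
    return _wrap_mixedlm(fit, df, groups, reml, scale)


def _wrap_mixedlm(fit, df: pd.DataFrame, groups: str, reml: bool, scale: float = 1.0) -> ModelFit:
    fe = fit.fe_params
    names = list(fe.index)
    vcov = pd.DataFrame(
        np.asarray(fit.cov_params().loc[names, names]), index=names, columns=names
    )
    s2_int = float(np.asarray(fit.cov_re).ravel()[0]) if fit.cov_re.size else 0.0
    sizes = df.groupby(groups).size()
    return ModelFit(
        coef=fe.copy() * scale,
        vcov=vcov * scale**2,
        s2_int=max(s2_int, 0.0) * scale**2,
        s2_res=float(fit.scale) * scale**2,
        n=int(len(df)),
        n_participants=int(sizes.size),
        n_cluster=float(sizes.mean()),
        converged=bool(fit.converged),
        method="reml" if reml else "ml",
    )


def cell_means_fit(
    data: pd.DataFrame,
    outcome: str,
    cells: list[str],
    cell_col: str = "cell",
    groups: str = "participant",
    reml: bool = True,
) -> ModelFit:
    """Cell-means random-intercept model: one named mean per design cell.

    Uses the no-intercept parameterization so each coefficient IS a cell
    mean and hypothesis constraints map directly onto named parameters.
    Coefficients are renamed from patsy's ``C(cell)[...]`` to the bare cell
    labels, ordered as in ``cells``.
    """
    df = data.dropna(subset=[outcome, cell_col]).copy()
    present = set(df[cell_col].unique())
    missing = [c for c in cells if c not in present]
    if missing:
        raise ValueError(f"design cells absent from data: {missing}")
    df = df[df[cell_col].isin(cells)]
    fit = fit_random_intercept_model(
        df, outcome, fixed=f"0 + C({cell_col})", groups=groups, reml=reml
    )
    rename = {}
    for name in fit.coef.index:
        label = name.split("[", 1)[1].rstrip("]") if "[" in name else name
        label = label.removeprefix("T.")
        rename[name] = label
    fit.coef = fit.coef.rename(rename).loc[cells]
    fit.vcov = fit.vcov.rename(index=rename, columns=rename).loc[cells, cells]
    return fit


def build_eq2_design(
    data: pd.DataFrame,
    detail_field: str = "internal_details",
    outcome_field: str = "zygo_pct",
    group_field: str = "group",
    participant_field: str = "participant",
    dysphoric_label: str = "dysphoric",
) -> tuple[pd.DataFrame, list]:
    """Within/between-person decomposition of episodic detail, by group.

    Builds the design for the detail-affect model: group dummies
    (``group1`` = 1 for dysphoric, ``group2`` = 1 for non-dysphoric), the
    grand-mean-centred participant mean of episodic detail crossed with the
    group dummies (between-person slopes ``beta3``/``beta4``), and the
    participant-mean-centred detail crossed with the dummies (within-person
    slopes ``gamma1``/``gamma2``).  Returns the design frame (with the
    outcome and participant id) and the list of participants contributing a
    single trial, whose within-person term is structurally zero.
    """
    df = data.dropna(subset=[detail_field, outcome_field]).copy()
    if df[group_field].nunique() < 2:
        raise ValueError("both groups must be present")
    pmean = df.groupby(participant_field)[detail_field].transform("mean")
    # grand mean over participants (not trials), so each person counts once
    grand = df.groupby(participant_field)[detail_field].mean().mean()
    between = pmean - grand
    within = df[detail_field] - pmean

    g1 = (df[group_field] == dysphoric_label).astype(float)
    g2 = 1.0 - g1
    design = pd.DataFrame(
        {
            participant_field: df[participant_field],
            outcome_field: df[outcome_field],
            "group1": g1,
            "group2": g2,
            "between_g1": between * g1,
            "between_g2": between * g2,
            "within_g1": within * g1,
            "within_g2": within * g2,
        },
        index=df.index,
    )
    singletons = (
        df.groupby(participant_field).size().pipe(lambda s: s[s == 1]).index.tolist()
    )
    return design, singletons


EQ2_TERMS = ["group1", "group2", "between_g1", "between_g2", "within_g1", "within_g2"]


def fit_detail_affect_model(
    data: pd.DataFrame,
    detail_field: str = "internal_details",
    outcome_field: str = "zygo_pct",
    reml: bool = True,
    **kwargs,
) -> ModelFit:
    """Fit the detail-affect multilevel model on one valence class.

    Coefficients: ``group1``/``group2`` (cell means at average detail),
    ``between_g1``/``between_g2`` (between-person detail slopes) and
    ``within_g1``/``within_g2`` (within-person detail slopes), with a
    participant random intercept.
    """
    design, _ = build_eq2_design(data, detail_field, outcome_field, **kwargs)
    fixed = "0 + " + " + ".join(EQ2_TERMS)
    return fit_random_intercept_model(design, outcome_field, fixed=fixed)


def ols_fit(data: pd.DataFrame, outcome: str, fixed: str = "1") -> ModelFit:
    """Participant-level ordinary regression wrapped as a ModelFit.

    Used for one-row-per-participant analyses (symptom-severity and
    affect-questionnaire tests), where there is no clustering and the
    effective sample size is simply the number of participants.
    """
    import statsmodels.formula.api as smf

    df = data.dropna(subset=[outcome]).copy()
    fit = smf.ols(f"{outcome} ~ {fixed}", data=df).fit()
    names = list(fit.params.index)
    return ModelFit(
        coef=fit.params.copy(),
        vcov=pd.DataFrame(np.asarray(fit.cov_params()), index=names, columns=names),
        s2_int=0.0,
        s2_res=float(fit.mse_resid),
        n=int(fit.nobs),
        n_participants=int(fit.nobs),
        n_cluster=1.0,
        converged=True,
        method="ols",
    )
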