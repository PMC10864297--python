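"""The registered analysis battery and the sequential updating design.

Each test fits a random-intercept multilevel model, extracts the normal
posterior approximation of the relevant cell means or slopes, and weighs a
set of informative hypotheses with approximate adjusted fractional Bayes
factors.  The battery mirrors a registered-report design:

* manipulation checks — did emotional memories move the facial muscles;
* Test 1 — episodic detail: overgeneral bias vs negativity bias vs null;
* Test 2A — affective responses to memories (fEMG or self-report valence);
* Test 2B — affective responses to movies, conditional on the 2A verdict;
* Test 3 — within/between-person coupling of detail and affect;
* exploratory suite — positive attenuation, habituation over trials,
  symptom-severity regressions, and pre/post affect-questionnaire tests;
* sequential design — recompute Tests 1 and 2A at N = 40, 50, ..., 80 and
  stop once both leading posterior model probabilities reach 0.80.

Sign conventions (documented once, used throughout): a *stronger* emotional
response means more zygomaticus activity on positive trials, more
corrugator activity on negative trials, higher valence ratings on positive
trials and *lower* valence ratings on negative trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

import roambait.evidence as ev

from . import mixedmodels as mm

__all__ = [
    "BatteryReport",
    "SequentialState",
    "run_manipulation_checks",
    "run_test1",
    "run_test2a",
    "run_test2b",
    "run_test3",
    "run_exploratory_suite",
    "run_sequential_design",
    "run_battery",
]

GROUPS = {"dysphoric": "dys", "non-dysphoric": "non"}
AFFECT_CELLS = ["dys_positive", "dys_negative", "non_positive", "non_negative"]

# hypothesis batteries on the four group x valence cell means; direction of
# "response strength" per outcome family is absorbed into the constraints
DETAIL_HYPOTHESES = {
    "H1": "dys_positive < non_positive & dys_negative < non_negative",  # overgeneral
    "H2": "dys_positive < non_positive & dys_negative > non_negative",  # negativity
    "H0": "dys_positive = non_positive & dys_negative = non_negative",
}
FEMG_HYPOTHESES = DETAIL_HYPOTHESES  # more corrugator = stronger negative affect
VALENCE_HYPOTHESES = {
    # lower valence on negative trials = enhanced negative affect
    "H1": "dys_positive < non_positive & dys_negative > non_negative",  # overgeneral
    "H2": "dys_positive < non_positive & dys_negative < non_negative",  # negativity
    "H0": "dys_positive = non_positive & dys_negative = non_negative",
}


@dataclass
class BatteryReport:
    """All evidence tables of one battery run, with provenance."""

    sections: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def add(self, name: str, section: dict) -> None:
        self.sections[name] = section


@dataclass
class SequentialState:
    """Where a sequential Bayesian updating run ended."""

    current_N: int
    trajectory: list[dict]
    stopped: bool
    stop_reason: str  # "evidence" | "max_N"


def _section(model: mm.ModelFit | None, tables: dict[str, pd.DataFrame],
             winner: str | None = None, notes: str = "") -> dict:
    out = {"tables": tables, "notes": notes}
    if model is not None:
        out["model"] = model.to_dict()
    if winner is not None:
        out["winner"] = winner
    return out


def _winner(table: pd.DataFrame) -> str:
    return str(table.loc[table["PostP"].idxmax(), "hypothesis"])


def _cell_frame(data: pd.DataFrame, outcome: str, conditions=("positive", "negative")) -> pd.DataFrame:
    df = data[data["condition"].isin(conditions)].copy()
    df["cell"] = df["group"].map(GROUPS) + "_" + df["condition"]
    return df.dropna(subset=[outcome])


def _affect_frame(data: pd.DataFrame) -> pd.DataFrame:
    """Combined fEMG outcome: zygomaticus on positive, corrugator on negative trials."""
    pos = data[data["condition"] == "positive"].copy()
    pos["affect"] = pos["zygo_pct"]
    neg = data[data["condition"] == "negative"].copy()
    neg["affect"] = neg["corr_pct"]
    df = pd.concat([pos, neg], ignore_index=True)
    df["cell"] = df["group"].map(GROUPS) + "_" + df["condition"]
    return df.dropna(subset=["affect"])


def _evaluate_cells(
    df: pd.DataFrame,
    outcome: str,
    hypotheses: dict[str, str],
    cells: list[str] = AFFECT_CELLS,
    fraction: float = 2.0,
    draws: int = ev.DEFAULT_DRAWS,
    seed: int = 0,
    include_failsafe: bool = True,
) -> tuple[mm.ModelFit, pd.DataFrame]:
    fit = mm.cell_means_fit(df, outcome, cells)
    results = ev.evaluate_hypotheses(
        fit.posterior(), hypotheses, fraction=fraction, draws=draws, seed=seed,
        include_failsafe=include_failsafe,
    )
    return fit, ev.evidence_table(results)


def _affect_posterior_per_muscle(df: pd.DataFrame) -> tuple[ev.PosteriorApprox, dict]:
    """Joint posterior of the four affect cell means from per-muscle models.

    Zygomaticus (positive trials) and corrugator (negative trials) carry
    very different residual variances, so each muscle gets its own
    random-intercept model; the joint normal approximation is block
    diagonal (the blocks come from disjoint trials) and the effective
    sample size is averaged over the two models.
    """
    fits = {}
    for cond in ("positive", "negative"):
        sub = df[df["condition"] == cond]
        fits[cond] = mm.cell_means_fit(sub, "affect",
                                       [f"dys_{cond}", f"non_{cond}"])
    names = AFFECT_CELLS
    G = len(names)
    mean = np.empty(G)
    sigma = np.zeros((G, G))
    for cond, fit in fits.items():
        post = fit.posterior()
        idx = [names.index(n) for n in post.names]
        mean[idx] = post.gamma_hat
        sigma[np.ix_(idx, idx)] = post.sigma
    n_eff = float(np.mean([f.n_eff for f in fits.values()]))
    joint = ev.PosteriorApprox(mean, sigma, n_eff, names=tuple(names))
    summary = {cond: fit.to_dict() for cond, fit in fits.items()}
    return joint, summary


def run_test1(data: pd.DataFrame, fraction: float = 2.0,
              draws: int = ev.DEFAULT_DRAWS, seed: int = 0) -> dict:
    """Episodic detail: overgeneral bias (H1) vs negativity bias (H2) vs null."""
    df = _cell_frame(data, "internal_details")
    fit, table = _evaluate_cells(df, "internal_details", DETAIL_HYPOTHESES,
                                 fraction=fraction, draws=draws, seed=seed)
    return _section(fit, {"evidence": table}, winner=_winner(table))


def run_test2a(data: pd.DataFrame, outcome: str = "femg", fraction: float = 2.0,
               draws: int = ev.DEFAULT_DRAWS, seed: int = 0,
               combined_model: bool = False) -> dict:
    """Affective responses to memories, on fEMG or self-reported valence.

    With the fEMG outcome the default fits one model per muscle and joins
    the cell-mean posteriors block-diagonally, because the two muscles'
    percent-change scales have very different residual variances; a single
    pooled-variance cell-means model is available via ``combined_model``.
    """
    if outcome == "femg":
        df, hyps = _affect_frame(data), FEMG_HYPOTHESES
        if not combined_model:
            post, models = _affect_posterior_per_muscle(df)
            results = ev.evaluate_hypotheses(post, hyps, fraction=fraction,
                                             draws=draws, seed=seed)
            table = ev.evidence_table(results)
            sec = _section(None, {"evidence": table}, winner=_winner(table),
                           notes="outcome=femg, per-muscle models")
            sec["models"] = models
            return sec
        col = "affect"
    elif outcome == "valence":
        df, col, hyps = _cell_frame(data, "valence"), "valence", VALENCE_HYPOTHESES
    else:
        raise ValueError("outcome must be 'femg' or 'valence'")
    fit, table = _evaluate_cells(df, col, hyps, fraction=fraction, draws=draws, seed=seed)
    return _section(fit, {"evidence": table}, winner=_winner(table),
                    notes=f"outcome={outcome}")


def run_test2b(data_movies: pd.DataFrame, test2a_winner: str, outcome: str = "femg",
               fraction: float = 2.0, draws: int = ev.DEFAULT_DRAWS, seed: int = 0) -> dict:
    """Movie affect, conditional on Test 2A: run the winning directional
    pattern against its complement; registered to be skipped when 2A
    favoured the null or the fail-safe."""
    if test2a_winner not in ("H1", "H2"):
        return _section(None, {}, winner="skipped",
                        notes=f"skipped: Test 2A favoured {test2a_winner}")
    hyp_source = FEMG_HYPOTHESES if outcome == "femg" else VALENCE_HYPOTHESES
    hyps = {"H1": hyp_source[test2a_winner]}
    if outcome == "femg":
        post, _ = _affect_posterior_per_muscle(_affect_frame(data_movies))
        results = ev.evaluate_hypotheses(post, hyps, fraction=fraction,
                                         draws=draws, seed=seed)
        table = ev.evidence_table(results)
        fit = None
    else:
        fit, table = _evaluate_cells(_cell_frame(data_movies, "valence"), "valence",
                                     hyps, fraction=fraction, draws=draws, seed=seed)
    return _section(fit, {"evidence": table}, winner=_winner(table),
                    notes=f"pattern from Test 2A {test2a_winner}; outcome={outcome}")


def run_test3(data: pd.DataFrame, valence_class: str = "positive",
              outcome: str | None = None, detail_field: str = "internal_details",
              fraction: float = 2.0, draws: int = ev.DEFAULT_DRAWS, seed: int = 0) -> dict:
    """Detail-affect coupling within one valence class.

    Fits the within/between-person centred multilevel model and evaluates
    directional hypothesis sets on the within-person slopes (``gamma``),
    the between-person slopes (``beta``), and their group differences.
    """
    if outcome is None:
        outcome = "zygo_pct" if valence_class == "positive" else "corr_pct"
    df = data[data["condition"] == valence_class]
    fit = mm.fit_detail_affect_model(df, detail_field, outcome)

    tables = {}
    specs = {
        "within_dysphoric": (["within_g1"], "within_g1"),
        "within_non_dysphoric": (["within_g2"], "within_g2"),
        "between_dysphoric": (["between_g1"], "between_g1"),
        "between_non_dysphoric": (["between_g2"], "between_g2"),
    }
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(len(specs) + 2)]
    for s, (label, (names, par)) in zip(seeds, specs.items()):
        hyps = {"H1": f"{par}>0", "H2": f"{par}<0", "H0": f"{par}=0"}
        results = ev.evaluate_hypotheses(
            fit.posterior(names), hyps, fraction=fraction, draws=draws,
            seed=s, include_failsafe=False,
        )
        tables[label] = ev.evidence_table(results)
    for s, (label, pair) in zip(seeds[len(specs):], {
        "within_group_difference": ("within_g1", "within_g2"),
        "between_group_difference": ("between_g1", "between_g2"),
    }.items()):
        a, b = pair
        hyps = {"H1": f"{a}>{b}", "H2": f"{a}<{b}", "H0": f"{a}={b}"}
        results = ev.evaluate_hypotheses(
            fit.posterior([a, b]), hyps, fraction=fraction, draws=draws,
            seed=s, include_failsafe=False,
        )
        tables[label] = ev.evidence_table(results)
    return _section(fit, tables, notes=f"valence_class={valence_class}, outcome={outcome}")


def run_manipulation_checks(data: pd.DataFrame, fraction: float = 2.0,
                            draws: int = ev.DEFAULT_DRAWS, seed: int = 0) -> dict:
    """Did emotional memories engage the facial muscles.

    Per group and muscle, on trial-level unstandardized amplitude means:
    recall vs baseline and emotional vs neutral three-hypothesis sets; plus
    the exploratory check that the standardized percent change differs
    from 0.
    """
    tables = {}
    ss = np.random.SeedSequence(seed)
    jobs = []
    for group in GROUPS:
        for muscle, cond in (("zygo", "positive"), ("corr", "negative")):
            jobs.append((group, muscle, cond))
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3 * len(jobs))]
    si = iter(seeds)
    for group, muscle, cond in jobs:
        gdf = data[data["group"] == group]
        tag = f"{GROUPS[group]}_{muscle}"

        # recall vs baseline on raw amplitudes (paired within trial)
        cdf = gdf[gdf["condition"] == cond]
        long = pd.concat([
            pd.DataFrame({"participant": cdf["participant"], "cell": "recall",
                          "amplitude": cdf[f"{muscle}_recall_mean"]}),
            pd.DataFrame({"participant": cdf["participant"], "cell": "baseline",
                          "amplitude": cdf[f"{muscle}_base_mean"]}),
        ], ignore_index=True)
        fit, table = _evaluate_cells(
            long, "amplitude",
            {"H1": "recall>baseline", "H2": "recall<baseline", "H0": "recall=baseline"},
            cells=["recall", "baseline"], fraction=fraction, draws=draws,
            seed=next(si), include_failsafe=False,
        )
        tables[f"{tag}_recall_vs_baseline"] = table

        # emotional vs neutral recall amplitudes
        edf = gdf[gdf["condition"].isin([cond, "neutral"])].copy()
        edf["cell"] = np.where(edf["condition"] == cond, "emotional", "neutral")
        fit, table = _evaluate_cells(
            edf, f"{muscle}_recall_mean",
            {"H1": "emotional>neutral", "H2": "emotional<neutral", "H0": "emotional=neutral"},
            cells=["emotional", "neutral"], fraction=fraction, draws=draws,
            seed=next(si), include_failsafe=False,
        )
        tables[f"{tag}_emotional_vs_neutral"] = table

        # exploratory: standardized response vs 0
        sdf = gdf[gdf["condition"] == cond].dropna(subset=[f"{muscle}_pct"])
        fit0 = mm.fit_random_intercept_model(sdf, f"{muscle}_pct", fixed="1")
        results = ev.evaluate_hypotheses(
            fit0.posterior(["Intercept"]),
            {"H1": "Intercept>0", "H2": "Intercept<0", "H0": "Intercept=0"},
            fraction=fraction, draws=draws, seed=next(si), include_failsafe=False,
        )
        tables[f"{tag}_standardized_vs_zero"] = ev.evidence_table(results)
    return _section(None, tables)


def run_exploratory_suite(data: pd.DataFrame, movies: pd.DataFrame | None = None,
                          panas: pd.DataFrame | None = None, symptom_col: str = "bdi",
                          fraction: float = 2.0, draws: int = ev.DEFAULT_DRAWS,
                          seed: int = 0) -> dict:
    """Post-hoc analyses: positive attenuation, habituation, symptom
    severity, and pre/post affect-questionnaire comparisons."""
    tables: dict[str, pd.DataFrame] = {}
    notes = []
    ss = np.random.SeedSequence(seed)
    seeds = iter(int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(64))

    # (a) positive attenuation vs negativity bias on memory (and movie) affect
    atten_hyps = {
        "H1": FEMG_HYPOTHESES["H2"],  # negativity bias
        "H2": "dys_positive < non_positive & dys_negative = non_negative",  # attenuation
    }
    for label, frame in (("memories", data),) + ((("movies", movies),) if movies is not None else ()):
        post, _ = _affect_posterior_per_muscle(_affect_frame(frame))
        results = ev.evaluate_hypotheses(post, atten_hyps, fraction=fraction,
                                         draws=draws, seed=next(seeds))
        table = ev.evidence_table(results)
        tables[f"attenuation_vs_negativity_{label}"] = table
        bfs = table.set_index("hypothesis")["BF_iu"]
        notes.append(f"{label}: BF_21 (attenuation vs negativity) = {bfs['H2'] / bfs['H1']:.3f}")

    # (b) habituation over the five same-valence trials
    for group in GROUPS:
        for muscle, cond in (("zygo", "positive"), ("corr", "negative")):
            gdf = data[(data["group"] == group) & (data["condition"] == cond)].copy()
            gdf["cell"] = "t" + gdf["condition_trial"].astype(int).astype(str)
            cells = [f"t{i}" for i in range(1, 6)]
            chain_down = ">".join(cells)
            chain_eq = "=".join(cells)
            _, table = _evaluate_cells(
                gdf, f"{muscle}_pct", {"H1": chain_down, "H0": chain_eq},
                cells=cells, fraction=fraction, draws=draws, seed=next(seeds),
            )
            tables[f"habituation_{GROUPS[group]}_{muscle}"] = table

    # (c) symptom-severity regressions within the dysphoric group
    dys = data[data["group"] == "dysphoric"]
    for label, cond, outcome in (
        ("details_positive", "positive", "internal_details"),
        ("details_negative", "negative", "internal_details"),
        ("zygo_positive", "positive", "zygo_pct"),
        ("corr_negative", "negative", "corr_pct"),
    ):
        means = (
            dys[dys["condition"] == cond]
            .groupby("participant")
            .agg(y=(outcome, "mean"), x=(symptom_col, "first"))
            .dropna()
        )
        fit = mm.ols_fit(means, "y", "x")
        results = ev.evaluate_hypotheses(
            fit.posterior(["x"]), {"H1": "x>0", "H2": "x<0", "H0": "x=0"},
            fraction=fraction, draws=draws, seed=next(seeds), include_failsafe=False,
        )
        tables[f"symptom_{label}"] = ev.evidence_table(results)

    # (d) affect-questionnaire group and change tests
    if panas is not None:
        for scale in ("pa", "na"):
            long = pd.concat([
                panas.assign(cell=panas["group"].map(GROUPS), score=panas[f"{scale}_pre"]),
                panas.assign(cell=panas["group"].map(GROUPS), score=panas[f"{scale}_post"]),
            ], ignore_index=True)
            direction = "dys<non" if scale == "pa" else "dys>non"
            _, table = _evaluate_cells(
                long, "score", {"H1": direction, "H0": "dys=non"},
                cells=["dys", "non"], fraction=fraction, draws=draws, seed=next(seeds),
            )
            tables[f"panas_{scale}_group"] = table

            delta = panas.assign(cell=panas["group"].map(GROUPS),
                                 delta=panas[f"{scale}_post"] - panas[f"{scale}_pre"])
            fit = mm.ols_fit(delta, "delta", "0 + C(cell)")
            fit.coef.index = [n.split("[", 1)[1].rstrip("]") for n in fit.coef.index]
            fit.vcov.index = fit.vcov.columns = fit.coef.index
            results = ev.evaluate_hypotheses(
                fit.posterior(["dys", "non"]),
                {"H1": "dys>non", "H2": "dys<non", "H0": "dys=non"},
                fraction=fraction, draws=draws, seed=next(seeds), include_failsafe=False,
            )
            tables[f"panas_{scale}_change"] = ev.evidence_table(results)
    return _section(None, tables, notes="; ".join(notes))


def _leading_postp(table: pd.DataFrame) -> float:
    return float(table["PostP"].max())


def run_sequential_design(
    source: pd.DataFrame | Callable[[int], dict],
    criterion: float = 0.80,
    n_min: int = 40,
    step: int = 10,
    n_max: int = 80,
    fraction: float = 2.0,
    draws: int = ev.DEFAULT_DRAWS,
    seed: int = 0,
) -> SequentialState:
    """Sequential Bayesian updating over the two primary tests.

    At N = n_min and after each group-balanced step of ``step`` (half per
    group, participants taken in arrival order) Tests 1 and 2A are
    recomputed; sampling stops once BOTH leading posterior model
    probabilities reach ``criterion``, else at ``n_max``.

    ``source`` is either a participant-ordered trial table or a callable
    ``N -> {"test1": PostP, "test2a": PostP}`` (e.g. a constructed evidence
    stream for design calibration).
    """
    if callable(source):
        evaluator = source
    else:
        data = source

        def evaluator(N: int) -> dict:
            sub = _first_n_participants(data, N)
            t1 = run_test1(sub, fraction=fraction, draws=draws, seed=seed)
            t2a = run_test2a(sub, "femg", fraction=fraction, draws=draws, seed=seed)
            return {
                "test1": _leading_postp(t1["tables"]["evidence"]),
                "test2a": _leading_postp(t2a["tables"]["evidence"]),
            }

    trajectory = []
    N = n_min
    while True:
        probs = evaluator(N)
        trajectory.append({"N": N, **probs})
        if all(p >= criterion for p in probs.values()):
            return SequentialState(N, trajectory, True, "evidence")
        if N >= n_max:
            return SequentialState(N, trajectory, True, "max_N")
        N += step


def _first_n_participants(data: pd.DataFrame, N: int) -> pd.DataFrame:
    """Group-balanced subset: the first N/2 participants per group, in order."""
    keep = []
    for _, gdf in data.groupby("group", sort=False):
        ids = gdf["participant"].drop_duplicates().iloc[: N // 2]
        keep.append(gdf[gdf["participant"].isin(ids)])
    out = pd.concat(keep, ignore_index=True)
    got = out["participant"].nunique()
    if got < N:
        raise ValueError(f"stream exhausted: only {got} participants available of {N}")
    return out


def run_battery(
    data: pd.DataFrame,
    movies: pd.DataFrame | None = None,
    panas: pd.DataFrame | None = None,
    fraction: float = 2.0,
    draws: int = ev.DEFAULT_DRAWS,
    seed: int = 0,
    sensitivity_fractions: tuple[float, ...] = (),
) -> BatteryReport:
    """Run the full battery on one trial table (plus optional side tables)."""
    report = BatteryReport(provenance={
        "seed": seed, "fraction": fraction, "draws": draws,
        "n_participants": int(data["participant"].nunique()),
        "n_trials": int(len(data)),
    })
    has_raw = {"zygo_recall_mean", "zygo_base_mean"}.issubset(data.columns)
    if has_raw:
        report.add("manipulation_checks",
                   run_manipulation_checks(data, fraction, draws, seed))
    report.add("test1", run_test1(data, fraction, draws, seed))
    t2a = run_test2a(data, "femg", fraction, draws, seed)
    report.add("test2a_femg", t2a)
    report.add("test2a_valence", run_test2a(data, "valence", fraction, draws, seed))
    if movies is not None:
        report.add("test2b", run_test2b(movies, t2a["winner"], "femg",
                                        fraction, draws, seed))
    for vc in ("positive", "negative"):
        report.add(f"test3_{vc}", run_test3(data, vc, fraction=fraction,
                                            draws=draws, seed=seed))
    report.add("exploratory",
               run_exploratory_suite(data, movies, panas, fraction=fraction,
                                     draws=draws, seed=seed))
    if sensitivity_fractions:
        # prior-fraction sensitivity of the primary episodic-detail test
        df = _cell_frame(data, "internal_details")
        fit = mm.cell_means_fit(df, "internal_details", AFFECT_CELLS)
        table = ev.sensitivity_over_fractions(
            fit.posterior(), DETAIL_HYPOTHESES,
            fractions=tuple(sensitivity_fractions), draws=draws, seed=seed,
        )
        report.add("sensitivity_test1", {"tables": {}, "notes": "",
                                         "sensitivity": table.to_dict("records")})
    return report
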