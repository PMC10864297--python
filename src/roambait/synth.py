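"""Synthetic autobiographical-memory (ROAM-style) datasets.

Emulates the study design downstream stages expect: two groups (dysphoric /
non-dysphoric), 13 memory trials per participant (5 positive, 5 negative,
3 neutral), participant random intercepts, and trial-level residual noise.
Four generative scenarios encode the competing theoretical accounts via the
SIGN pattern of the dysphoric-minus-non-dysphoric shift on emotional
material:

========================  ==========  ==========
scenario                  positive    negative
========================  ==========  ==========
overgeneral_bias          diminished  diminished
negativity_bias           diminished  enhanced
positive_attenuation      diminished  intact
null                      intact      intact
========================  ==========  ==========

"Diminished"/"enhanced" refer to the strength of the emotional response:
fewer/more episodic details, weaker/stronger zygomaticus (positive trials)
or corrugator (negative trials) reactivity, and less extreme self-reported
valence.  One global seed expands into per-participant substreams, so a
dataset can be extended with additional participants (the sequential design
adds 5 per group per step) without perturbing earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .emg import RawTrace

__all__ = ["ScenarioParams", "SyntheticDataset", "generate_trial_table",
           "generate_panas", "generate_raw_trace", "SCENARIOS"]

# direction of the dysphoric shift in emotional-response strength
# (positive-material shift, negative-material shift)
SCENARIOS: dict[str, tuple[float, float]] = {
    "overgeneral_bias": (-1.0, -1.0),
    "negativity_bias": (-1.0, +1.0),
    "positive_attenuation": (-1.0, 0.0),
    "null": (0.0, 0.0),
}

# non-dysphoric cell means per outcome and condition (model units)
BASE_MEANS = {
    "internal_details": {"positive": 23.0, "negative": 19.5, "neutral": 15.3},
    "valence": {"positive": 85.0, "negative": 22.0, "neutral": 53.0},
    "zygo_pct": {"positive": 175.0, "negative": 4.0, "neutral": 10.0},
    "corr_pct": {"positive": -11.5, "negative": 18.0, "neutral": 1.0},
}
# trial-level residual SDs
SIGMA_RES = {"internal_details": 5.0, "valence": 12.0, "zygo_pct": 120.0, "corr_pct": 30.0}
# magnitude of a unit scenario shift, per outcome
EFFECT_UNITS = {"internal_details": 2.5, "valence": 8.0, "zygo_pct": 80.0, "corr_pct": 15.0}

OUTCOMES = list(BASE_MEANS)


@dataclass
class ScenarioParams:
    """Generative parameters for one synthetic study.

    ``effect_scale`` multiplies the per-outcome unit shifts (1.0 is a
    realistic study-sized effect; large values make the scenario trivially
    identifiable).  ``icc_target`` sets the participant random-intercept
    share of outcome variance; ``detail_mode`` chooses rounded-Gaussian
    (default, mean and variance independently controllable) or Poisson
    detail counts.
    """

    scenario: str = "null"
    n_per_group: int = 40
    trials: tuple[int, int, int] = (5, 5, 3)  # positive, negative, neutral
    icc_target: float = 0.3
    effect_scale: float = 1.0
    group_effects: dict | None = None  # per-outcome/per-condition overrides
    slope_detail_affect: tuple[float, float] = (0.0, 0.0)  # (dysphoric, non-dysphoric)
    detail_mode: str = "gaussian"  # or "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; one of {list(SCENARIOS)}")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")
        if not 0.0 <= self.icc_target < 1.0:
            raise ValueError("icc_target must lie in [0, 1)")
        if self.detail_mode not in ("gaussian", "poisson"):
            raise ValueError("detail_mode must be 'gaussian' or 'poisson'")

    def shifts(self) -> dict[str, dict[str, float]]:
        """Dysphoric-minus-non-dysphoric mean shift per outcome and condition."""
        s_pos, s_neg = SCENARIOS[self.scenario]
        out: dict[str, dict[str, float]] = {}
        for outcome in OUTCOMES:
            u = EFFECT_UNITS[outcome] * self.effect_scale
            if outcome == "zygo_pct":
                shift = {"positive": s_pos * u, "negative": 0.0, "neutral": 0.0}
            elif outcome == "corr_pct":
                shift = {"positive": 0.0, "negative": s_neg * u, "neutral": 0.0}
            elif outcome == "valence":
                # enhanced negative response = more negative (lower) valence
                shift = {"positive": s_pos * u, "negative": -s_neg * u, "neutral": 0.0}
            else:
                shift = {"positive": s_pos * u, "negative": s_neg * u, "neutral": 0.0}
            out[outcome] = shift
        if self.group_effects:
            for outcome, per_cond in self.group_effects.items():
                if outcome not in out:
                    raise ValueError(f"unknown outcome in group_effects: {outcome!r}")
                out[outcome].update(per_cond)
        return out


@dataclass
class SyntheticDataset:
    """A generated trial table with its generating truth (and optional traces)."""

    trial_table: pd.DataFrame
    truth: dict
    traces: list[RawTrace] = field(default_factory=list)


def _participant_rng(seed: int, group_idx: int, pid: int) -> np.random.Generator:
    # stable per-participant substream: extending the sample never
    # perturbs earlier participants
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(group_idx, pid)))


def generate_trial_table(params: ScenarioParams, material: str = "memories") -> SyntheticDataset:
    """Generate one synthetic trial table under a scenario.

    Outcomes per trial: internal/external episodic detail counts, valence
    (truncated to [0, 100]), standardized zygomaticus/corrugator percent
    change, and the unstandardized recall/baseline amplitude means that the
    manipulation checks need.  ``material="movies"`` emulates the
    movie-watching session with (2, 2, 1) trials per participant under the
    same scenario shifts.
    """
    trials = params.trials if material == "memories" else (2, 2, 1)
    shifts = params.shifts()
    icc = params.icc_target
    rows = []
    conditions = (
        ["positive"] * trials[0] + ["negative"] * trials[1] + ["neutral"] * trials[2]
    )
    for group_idx, group in enumerate(["non-dysphoric", "dysphoric"]):
        for pid in range(params.n_per_group):
            rng = _participant_rng(params.seed, group_idx, pid)
            if material != "memories":
                rng = np.random.default_rng(rng.integers(2**31))
            participant = f"{'D' if group == 'dysphoric' else 'N'}{pid + 1:03d}"
            order = rng.permutation(len(conditions))
            intercepts = {
                o: rng.normal(0.0, SIGMA_RES[o] * np.sqrt(icc / (1.0 - icc)))
                for o in OUTCOMES
            }
            bdi = float(np.clip(rng.normal(23, 5), 16, 50)) if group == "dysphoric" \
                else float(np.clip(rng.normal(5, 3), 0, 15))
            seen: dict[str, int] = {}
            slope = params.slope_detail_affect[0 if group == "dysphoric" else 1]
            for t_idx, cond_i in enumerate(order, start=1):
                cond = conditions[cond_i]
                seen[cond] = seen.get(cond, 0) + 1
                row = {
                    "participant": participant,
                    "group": group,
                    "condition": cond,
                    "trial_index": t_idx,
                    "condition_trial": seen[cond],
                    "bdi": bdi,
                }
                is_dys = group == "dysphoric"
                vals = {}
                for outcome in OUTCOMES:
                    mean = BASE_MEANS[outcome][cond] + (shifts[outcome][cond] if is_dys else 0.0)
                    vals[outcome] = mean + intercepts[outcome] + rng.normal(0, SIGMA_RES[outcome])
                if params.detail_mode == "poisson":
                    lam = max(
                        BASE_MEANS["internal_details"][cond]
                        + (shifts["internal_details"][cond] if is_dys else 0.0)
                        + intercepts["internal_details"],
                        0.1,
                    )
                    vals["internal_details"] = float(rng.poisson(lam))
                else:
                    vals["internal_details"] = float(max(round(vals["internal_details"]), 0))
                # optional trial-level coupling: detail pushes the affective response
                detail_dev = vals["internal_details"] - BASE_MEANS["internal_details"][cond]
                if slope != 0.0 and cond != "neutral":
                    target = "zygo_pct" if cond == "positive" else "corr_pct"
                    vals[target] += slope * detail_dev
                vals["valence"] = float(np.clip(vals["valence"], 0.0, 100.0))
                row.update(vals)
                row["external_details"] = float(max(round(rng.normal(3.3, 2.5)), 0))
                # unstandardized amplitudes consistent with the percent change
                for muscle, pct in (("zygo", vals["zygo_pct"]), ("corr", vals["corr_pct"])):
                    base_amp = max(rng.normal(2.0, 0.2), 0.5)
                    row[f"{muscle}_base_mean"] = base_amp
                    row[f"{muscle}_recall_mean"] = base_amp * max(1.0 + pct / 100.0, 0.0)
                rows.append(row)
    table = pd.DataFrame(rows)
    truth = {
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(params).items()},
        "material": material,
        "shifts": shifts,
        "base_means": BASE_MEANS,
        "sigma_res": SIGMA_RES,
    }
    return SyntheticDataset(trial_table=table, truth=truth)


def generate_detail_affect_data(
    beta: tuple[float, float, float, float] = (10.0, 20.0, 1.5, -0.5),
    gamma: tuple[float, float] = (2.0, 0.0),
    n_per_group: int = 40,
    n_trials: int = 13,
    icc: float = 0.3,
    sigma_res: float = 30.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Trial table with a known detail-affect regression structure.

    The outcome follows the within/between-person centred model exactly:
    group cell means ``beta[0]``/``beta[1]``, between-person detail slopes
    ``beta[2]``/``beta[3]``, within-person slopes ``gamma`` (dysphoric,
    non-dysphoric), a participant random intercept sized from ``icc``, and
    residual SD ``sigma_res``.  Centring uses the same empirical rule the
    model fit applies, so the generating coefficients are the estimands.
    Used for parameter-recovery studies.
    """
    rng = np.random.default_rng(seed)
    sigma_int = sigma_res * np.sqrt(icc / (1.0 - icc))
    rows = []
    for group_idx, group in enumerate(["non-dysphoric", "dysphoric"]):
        for pid in range(n_per_group):
            participant = f"{'D' if group == 'dysphoric' else 'N'}{pid + 1:03d}"
            details = rng.normal(20.0 + rng.normal(0, 4.0), 3.0, n_trials)
            for j in range(n_trials):
                rows.append({
                    "participant": participant, "group": group,
                    "condition": "positive", "trial_index": j + 1,
                    "internal_details": details[j],
                })
    df = pd.DataFrame(rows)
    pmean = df.groupby("participant")["internal_details"].transform("mean")
    grand = df.groupby("participant")["internal_details"].mean().mean()
    between, within = pmean - grand, df["internal_details"] - pmean
    g1 = (df["group"] == "dysphoric").astype(float)
    g2 = 1.0 - g1
    intercepts = df["participant"].map(
        {p: rng.normal(0, sigma_int) for p in df["participant"].unique()}
    )
    df["affect"] = (
        beta[0] * g1 + beta[1] * g2
        + beta[2] * between * g1 + beta[3] * between * g2
        + gamma[0] * within * g1 + gamma[1] * within * g2
        + intercepts + rng.normal(0, sigma_res, len(df))
    )
    return df


def generate_panas(params: ScenarioParams) -> pd.DataFrame:
    """Participant-level positive/negative affect scores before and after the task.

    Negative affect is elevated in the dysphoric group; positive affect is
    equal between groups with a small post-task dip in the non-dysphoric
    group, matching the kind of pattern a mood-induction session produces.
    """
    rows = []
    for group_idx, group in enumerate(["non-dysphoric", "dysphoric"]):
        for pid in range(params.n_per_group):
            rng = _participant_rng(params.seed, group_idx, pid)
            rng = np.random.default_rng(rng.integers(2**31, size=3)[-1])
            participant = f"{'D' if group == 'dysphoric' else 'N'}{pid + 1:03d}"
            dys = group == "dysphoric"
            pa_pre = rng.normal(26.5, 7.0)
            pa_post = pa_pre + rng.normal(-1.6 if not dys else 0.3, 3.0)
            na_pre = rng.normal(17.6 if dys else 10.9, 4.0 if dys else 1.5)
            na_post = na_pre + rng.normal(1.2, 2.0)
            rows.append(
                {"participant": participant, "group": group,
                 "pa_pre": pa_pre, "pa_post": pa_post,
                 "na_pre": max(na_pre, 10.0), "na_post": max(na_post, 10.0)}
            )
    return pd.DataFrame(rows)


def generate_raw_trace(
    participant: str = "N001",
    muscle: str = "zygomaticus",
    condition: str = "positive",
    trial_index: int = 1,
    pct_target: float = 50.0,
    burst_amplitude: float = 1.0,
    noise_sd: float = 1.0,
    artifact_rate: float = 0.0,
    baseline_s: int = 4,
    event_s: int = 60,
    rate: int = 1000,
    seed: int | np.random.Generator = 0,
    session: int = 2,
) -> RawTrace:
    """Synthesize one raw EMG trace whose percent change targets ``pct_target``.

    Baseline samples are broadband Gaussian noise of SD ``noise_sd``; event
    samples are bursts of SD ``burst_amplitude * (1 + pct_target/100)``.
    Because the conditioned, rectified amplitude is proportional to the
    sample SD, the downstream percent change matches ``pct_target`` in
    expectation when ``burst_amplitude == noise_sd`` (the default scaling),
    and is invariant to multiplying both by a common gain.  Artifacts are
    rare one-second spikes (30x amplitude) injected at ``artifact_rate``
    per event second.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if baseline_s <= 0 or event_s <= 0:
        raise ValueError("durations must be positive")
    event_scale = burst_amplitude * max(1.0 + pct_target / 100.0, 0.05)
    baseline = rng.normal(0.0, noise_sd, baseline_s * rate)
    event = rng.normal(0.0, event_scale, event_s * rate)
    if artifact_rate > 0:
        for s in range(event_s):
            if rng.random() < artifact_rate:
                event[s * rate:(s + 1) * rate] *= 30.0
    return RawTrace(
        samples=np.concatenate([baseline, event]),
        participant=participant,
        muscle=muscle,
        condition=condition,
        trial_index=trial_index,
        session=session,
        baseline_s=baseline_s,
        event_s=event_s,
        rate=rate,
    )
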