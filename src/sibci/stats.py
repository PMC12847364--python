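"""Chance-level thresholds, permutation nulls, effect sizes, discard analysis.

The significance threshold for a k-class decoding problem with n trials
follows the inverse binomial cumulative distribution rule: the smallest
correct-count c with ``BinomCDF(c; n, 1/k) >= 1 - alpha`` defines the
threshold ``100 * c / n`` percent.  Because empirical chance exceeds the
theoretical 1/k level in finite samples, this is the appropriate
benchmark for cross-validated accuracies.

The permutation test shuffles trial labels and re-runs the *entire*
decoding pipeline per permutation; the empirical p-value uses the
standard add-one rank formula and can therefore never be exactly zero.
A one-sample t comparison of the null distribution against the observed
accuracy is reported alongside (it treats the observed value as a fixed
scalar, which is statistically unconventional; both are labeled).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sst

from .config import AnalysisConfig
from .decode import ScenarioResult, ScenarioSpec, crossvalidate_scenario
from .preprocess import EpochSet
from .seeding import derive_seed


@dataclass(frozen=True)
class SignificanceThreshold:
    n_trials: int
    n_classes: int
    alpha: float
    threshold_pct: float  # rounded to one decimal

    @property
    def chance_pct(self) -> float:
        return 100.0 / self.n_classes


def binomial_threshold(n_trials: int, n_classes: int, alpha: float = 0.05) -> SignificanceThreshold:
    """Inverse-binomial-CDF significance threshold, in percent (one decimal)."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    p = 1.0 / n_classes
    c = int(sst.binom.ppf(1 - alpha, n_trials, p))
    # ppf returns the smallest c with CDF >= 1-alpha; guard the edge where
    # floating error lands one count low.
    while sst.binom.cdf(c, n_trials, p) < 1 - alpha:
        c += 1
    return SignificanceThreshold(
        n_trials=n_trials,
        n_classes=n_classes,
        alpha=alpha,
        threshold_pct=round(100.0 * c / n_trials, 1),
    )


def chance_band(n_trials: int, n_classes: int, coverage: float = 0.95) -> tuple[float, float]:
    """Two-sided binomial band (percent) around the 1/k chance level."""
    p = 1.0 / n_classes
    lo = (1 - coverage) / 2
    return (
        100.0 * sst.binom.ppf(lo, n_trials, p) / n_trials,
        100.0 * sst.binom.ppf(1 - lo, n_trials, p) / n_trials,
    )


def empirical_p_value(null_values: np.ndarray, observed: float) -> float:
    """Add-one permutation p-value: (1 + #{null >= observed}) / (n + 1)."""
    null_values = np.asarray(null_values, float)
    return (1 + int(np.sum(null_values >= observed))) / (null_values.size + 1)


@dataclass
class PermutationResult:
    observed_pct: float
    null_pct: np.ndarray
    empirical_p: float
    #: one-sample t of the null distribution against the observed scalar
    t_stat: float
    t_p: float
    seed: int
    warning: str | None = None


def permutation_null(
    epochs: EpochSet,
    scenario: ScenarioSpec,
    cfg: AnalysisConfig,
    n_perm: int,
    seed: int,
    observed: ScenarioResult | None = None,
) -> PermutationResult:
    """Label-shuffling null distribution of the full decoding pipeline."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if observed is None:
        observed = crossvalidate_scenario(epochs, scenario, cfg, derive_seed(seed, "obs"))
    obs = observed.mean_accuracy

    sub = epochs.select_tasks(scenario.tasks)
    nulls = np.empty(n_perm)
    for i in range(n_perm):
        rng = np.random.default_rng(derive_seed(seed, "perm", i))
        shuffled = sub.trials.copy()
        shuffled["task"] = rng.permutation(shuffled["task"].to_numpy())
        perm_epochs = EpochSet(
            data=sub.data,
            fs=sub.fs,
            window_s=sub.window_s,
            trials=shuffled,
            participant_id=sub.participant_id,
        )
        res = crossvalidate_scenario(perm_epochs, scenario, cfg, derive_seed(seed, "permcv", i))
        nulls[i] = res.mean_accuracy

    emp_p = empirical_p_value(nulls, obs)
    if len(nulls) >= 2 and nulls.std(ddof=1) > 0:
        t_stat, t_p = sst.ttest_1samp(nulls, obs)
    else:
        t_stat, t_p = np.nan, np.nan
    warning = None
    if n_perm < 19:
        warning = (
            f"n_perm={n_perm} cannot resolve p below {1 / (n_perm + 1):.3f}; "
            "alpha=0.05 decisions need n_perm >= 19"
        )
    return PermutationResult(
        observed_pct=obs,
        null_pct=nulls,
        empirical_p=emp_p,
        t_stat=float(t_stat),
        t_p=float(t_p),
        seed=seed,
        warning=warning,
    )


def compare_conditions(x, y) -> dict:
    """Paired t-test and paired Cohen's d = mean(x-y) / sd(x-y)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must be equal-length samples of size >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        return {"t": np.nan, "p": np.nan, "cohens_d": np.nan, "degenerate": True}
    t, p = sst.ttest_rel(x, y)
    return {
        "t": float(t),
        "p": float(p),
        "cohens_d": float(d.mean() / sd),
        "degenerate": False,
    }


def correlate(a, b, method: str = "pearson") -> dict:
    """Product-moment (default) or rank correlation with two-sided p."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("a and b must be equal-length samples of size >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return {"r": np.nan, "p": np.nan, "degenerate": True}
    if method == "pearson":
        r, p = sst.pearsonr(a, b)
    elif method == "spearman":
        r, p = sst.spearmanr(a, b)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return {"r": float(r), "p": float(p), "degenerate": False}


@dataclass
class DiscardComparison:
    mode: str  # 'flagged_only' | 'flagged_plus_weak'
    accuracy_discarded: float
    accuracy_random_matched: float
    n_removed: int
    scenario: ScenarioSpec


def discard_analysis(
    epochs: EpochSet,
    scenario: ScenarioSpec,
    cfg: AnalysisConfig,
    mode: str,
    seed: int,
    per_class_matched: bool = True,
) -> DiscardComparison:
    """Self-evaluation trial-discard analysis vs matched random removal.

    Arm 1 removes the flagged trials (per ``mode``); arm 2 removes the
    same number of randomly chosen trials — matched per class by default —
    and both arms re-run the scenario cross-validation.
    """
    if mode not in ("flagged_only", "flagged_plus_weak"):
        raise ValueError("mode must be 'flagged_only' or 'flagged_plus_weak'")
    if "self_eval" not in epochs.trials.columns:
        raise ValueError("epochs lack per-trial self_eval metadata")
    sub = epochs.select_tasks(scenario.tasks)
    bad = {"not_correct"} | ({"correct_not_well"} if mode == "flagged_plus_weak" else set())
    flagged = sub.trials["self_eval"].isin(bad).to_numpy()

    y = sub.labels
    for c in scenario.tasks:
        if np.all(flagged[y == c]):
            raise ValueError(f"mode {mode!r} would remove every trial of class {c!r}")

    keep_flagged = np.flatnonzero(~flagged)
    rng = np.random.default_rng(derive_seed(seed, "random-removal"))
    if per_class_matched:
        removed: list[int] = []
        for c in sorted(set(y)):
            idx = np.flatnonzero(y == c)
            n_rm = int(flagged[idx].sum())
            removed += list(rng.choice(idx, size=n_rm, replace=False))
    else:
        removed = list(
            rng.choice(len(y), size=int(flagged.sum()), replace=False)
        )
    keep_random = np.setdiff1d(np.arange(len(y)), np.array(removed, dtype=int))
    assert len(keep_random) == len(keep_flagged)  # audited: identical counts

    res_disc = crossvalidate_scenario(
        sub.select_trials(keep_flagged), scenario, cfg, derive_seed(seed, "cv-discard")
    )
    if int(flagged.sum()) == 0:
        res_rand = res_disc  # nothing removed in either arm: identical datasets
    else:
        res_rand = crossvalidate_scenario(
            sub.select_trials(keep_random), scenario, cfg, derive_seed(seed, "cv-random")
        )
    return DiscardComparison(
        mode=mode,
        accuracy_discarded=res_disc.mean_accuracy,
        accuracy_random_matched=res_rand.mean_accuracy,
        n_removed=int(flagged.sum()),
        scenario=scenario,
    )
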