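"""Run configuration: protocol, simulation and analysis settings.

Three dataclasses cover the whole pipeline:

* :class:`ProtocolConfig` — the experimental protocol being emulated
  (task set, trials per block, trial timing, acquisition constants).
* :class:`SimConfig` — the synthetic signal model (effect size, source
  topographies, band modulations, noise, subjective-response model).
* :class:`AnalysisConfig` — every analysis constant of the decoding
  pipeline (resampling rate, epoch window, filter bank, CSP filter
  count, number of selected features, forest size, CV scheme, alpha),
  each a named, overridable field.

``load_config`` reads all three from a single YAML file with top-level
keys ``protocol:``, ``sim:`` and ``analysis:``; missing keys take the
defaults below and unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

#: Canonical task vocabulary, in marker-code order (codes 1..7).
TASK_NAMES: tuple[str, ...] = ("L", "R", "F", "T", "SIkin", "SInoKin", "REST")

#: The two singing-imagery variants; at most one may enter a scenario
#: with more than two classes.
SI_TASKS: tuple[str, str] = ("SIkin", "SInoKin")


class ConfigError(ValueError):
    """A configuration value is out of range or a key is unknown."""


@dataclass(frozen=True)
class ProtocolConfig:
    """Experimental protocol: 7 tasks x 10 trials/block x 7 blocks at 500 Hz."""

    task_names: tuple[str, ...] = TASK_NAMES
    trials_per_task_per_block: int = 10
    n_blocks: int = 7
    fs: float = 500.0
    n_channels: int = 64
    blank_range_s: tuple[float, float] = (0.5, 1.5)
    ready_s: float = 0.5
    go_s: float = 0.5
    task_s: float = 4.0

    @property
    def n_tasks(self) -> int:
        return len(self.task_names)

    @property
    def trials_per_task(self) -> int:
        return self.trials_per_task_per_block * self.n_blocks

    @property
    def n_trials(self) -> int:
        return self.trials_per_task * self.n_tasks

    def __post_init__(self) -> None:
        if self.n_tasks < 1:
            raise ConfigError("task_names must be non-empty")
        if len(set(self.task_names)) != self.n_tasks:
            raise ConfigError("task_names must be unique")
        for t in self.task_names:
            if t not in TASK_NAMES:
                raise ConfigError(f"unknown task label {t!r}; expected subset of {TASK_NAMES}")
        if self.trials_per_task_per_block < 1 or self.n_blocks < 1:
            raise ConfigError("trials_per_task_per_block and n_blocks must be >= 1")
        if self.fs <= 0:
            raise ConfigError("fs must be positive")
        if self.n_channels < 2:
            raise ConfigError("n_channels must be >= 2")
        lo, hi = self.blank_range_s
        if not (0 < lo <= hi):
            raise ConfigError("blank_range_s must satisfy 0 < lo <= hi")
        for name in ("ready_s", "go_s", "task_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Synthetic signal model parameters.

    ``effect_size`` g scales the task-gated band-power modulation: during
    a trial of task ``t`` the variance of source ``s`` in band ``b`` is
    multiplied by ``1 + g * m[t, s, b]``.  ``g = 0`` makes all task
    conditions statistically identical by construction.
    """

    effect_size: float = 1.0
    #: Convex mixing of the SIkin topography toward the tongue topography
    #: (1.0 = identical topographies, maximal T/SIkin confusability).
    overlap_alpha: float = 0.3
    #: Relative modulation depth of SInoKin vs SIkin (small values push
    #: SInoKin toward REST).
    sinokin_depth: float = 0.5
    #: Modulation depth in the mu (8-12 Hz) band for a task's own source;
    #: negative = event-related desynchronization.
    mu_mod: float = -0.7
    #: Modulation depth in the beta (18-26 Hz) band.
    beta_mod: float = -0.5
    #: Std of each rhythmic source signal, in uV at the scalp peak channel.
    source_amp_uv: float = 6.0
    #: Std of the task-independent posterior alpha source.
    alpha_amp_uv: float = 4.0
    #: 1/f background: amplitude spectral density exponent and per-channel std.
    noise_exponent: float = 1.0
    noise_amp_uv: float = 4.0
    #: Gaussian spatial kernel width of source topographies, in normalized
    #: head-radius units of the 2-D projected montage.
    kernel_width: float = 0.35
    #: Self-evaluation category probabilities (correct, not_correct,
    #: correct_not_well).
    self_eval_probs: tuple[float, float, float] = (0.7, 0.15, 0.15)
    #: 'informative' ties flagged trials to degraded signal; 'uninformative'
    #: draws flags independently of the signal.
    self_eval_mode: str = "informative"
    #: Per-trial effect multiplier applied when a trial is flagged
    #: not_correct / correct_not_well in informative mode.
    flag_effect: tuple[float, float] = (0.0, 0.5)
    #: Correlation between a participant's effect-size multiplier and their
    #: kinesthetic KVIQ subscore.
    kviq_effect_corr: float = 0.6
    #: Lognormal sigma of the per-participant multiplier on g.
    participant_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        if not 0 <= self.overlap_alpha <= 1:
            raise ConfigError("overlap_alpha must be in [0, 1]")
        if self.sinokin_depth < 0:
            raise ConfigError("sinokin_depth must be >= 0")
        for name in ("mu_mod", "beta_mod"):
            if getattr(self, name) <= -1:
                raise ConfigError(f"{name} must be > -1 (variance must stay positive)")
        for name in ("source_amp_uv", "alpha_amp_uv", "noise_amp_uv", "kernel_width"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        p = self.self_eval_probs
        if len(p) != 3 or any(x < 0 for x in p) or abs(sum(p) - 1.0) > 1e-9:
            raise ConfigError("self_eval_probs must be 3 non-negative values summing to 1")
        if self.self_eval_mode not in ("informative", "uninformative"):
            raise ConfigError("self_eval_mode must be 'informative' or 'uninformative'")


#: Non-overlapping 4-Hz filter-bank passbands covering 4-40 Hz.
DEFAULT_BANDS: tuple[tuple[float, float], ...] = tuple(
    (float(lo), float(lo + 4)) for lo in range(4, 40, 4)
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Every analysis constant of the decoding pipeline, named and overridable."""

    target_fs: float = 250.0
    epoch_window_s: tuple[float, float] = (-0.5, 4.0)
    #: Covariance/feature window relative to imagery onset; the pre-onset
    #: segment serves only as filter edge padding.
    analysis_window_s: tuple[float, float] = (0.0, 4.0)
    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS
    fir_numtaps: int = 251
    n_csp_pairs: int = 5
    selector_k: int = 25
    discretize_bins: int = 5
    n_trees: int = 100
    n_folds: int = 10
    n_repeats: int = 5
    stratified: bool = True
    alpha: float = 0.05
    n_perm: int = 100
    #: Use the multiclass (joint-diagonalization) CSP even for 2-class
    #: scenarios, mirroring an analysis that ran one implementation for all
    #: scenario sizes.
    multiclass_csp_for_binary: bool = False
    #: Fit mRMR once per scenario on all trials instead of per training fold
    #: (leakage-prone literal reading; off by default).
    mrmr_outside_cv: bool = False
    #: Diagonal loading epsilon for rank-deficient covariances (0 disables).
    diag_loading: float = 0.0
    #: Use normalized variance fractions instead of raw variances in the
    #: log-variance features.
    normalized_logvar: bool = False
    #: Subtract the pre-onset mean instead of the whole-epoch mean
    #: (conventional baseline; deviates from the default whole-epoch rule).
    prestim_baseline: bool = False

    @property
    def n_csp_filters(self) -> int:
        return 2 * self.n_csp_pairs

    @property
    def n_features(self) -> int:
        return len(self.bands) * self.n_csp_filters

    def __post_init__(self) -> None:
        if self.target_fs <= 0:
            raise ConfigError("target_fs must be positive")
        t0, t1 = self.epoch_window_s
        a0, a1 = self.analysis_window_s
        if t1 <= t0:
            raise ConfigError("epoch_window_s must be increasing")
        if not (t0 <= a0 < a1 <= t1):
            raise ConfigError("analysis_window_s must lie within epoch_window_s")
        prev_hi = 0.0
        for lo, hi in self.bands:
            if not (0 < lo < hi):
                raise ConfigError(f"invalid band ({lo}, {hi})")
            if lo < prev_hi:
                raise ConfigError("bands must be ascending and non-overlapping")
            prev_hi = hi
        if prev_hi >= self.target_fs / 2:
            raise ConfigError("highest band edge must be below Nyquist")
        if self.fir_numtaps % 2 != 1 or self.fir_numtaps < 3:
            raise ConfigError("fir_numtaps must be odd and >= 3")
        if self.n_csp_pairs < 1:
            raise ConfigError("n_csp_pairs must be >= 1")
        if self.selector_k < 1 or self.selector_k > self.n_features:
            raise ConfigError("selector_k must be in [1, n_features]")
        if self.discretize_bins < 2:
            raise ConfigError("discretize_bins must be >= 2")
        if self.n_trees < 1:
            raise ConfigError("n_trees must be >= 1")
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ConfigError("n_repeats must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        if self.diag_loading < 0:
            raise ConfigError("diag_loading must be >= 0")


_SECTIONS = {"protocol": ProtocolConfig, "sim": SimConfig, "analysis": AnalysisConfig}

# Fields that are tuples (or tuples of tuples) in the dataclasses but arrive
# from YAML as lists.
_TUPLE_FIELDS = {
    "task_names",
    "blank_range_s",
    "self_eval_probs",
    "flag_effect",
    "epoch_window_s",
    "analysis_window_s",
    "bands",
}


def _coerce(key: str, value: object) -> object:
    if key in _TUPLE_FIELDS and isinstance(value, list):
        return tuple(tuple(v) if isinstance(v, list) else v for v in value)
    return value


def _build(cls: type, section: str, raw: dict) -> object:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in '{section}': {sorted(unknown)}")
    return cls(**{k: _coerce(k, v) for k, v in raw.items()})


def load_config(path) -> tuple[ProtocolConfig, SimConfig, AnalysisConfig]:
    """Load and validate a YAML config file; an empty file yields all defaults."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError("config file must contain a mapping")
    unknown = set(doc) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown top-level section(s): {sorted(unknown)}")
    out = []
    for section, cls in _SECTIONS.items():
        raw = doc.get(section, {}) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"section '{section}' must be a mapping")
        out.append(_build(cls, section, raw))
    return tuple(out)  # type: ignore[return-value]


def config_hash(*cfgs) -> str:
    """Short stable hash of one or more config dataclasses, for manifests."""
    import hashlib

    text = "|".join(repr(dataclasses.astuple(c)) for c in cfgs)
    return hashlib.sha256(text.encode()).hexdigest()[:12]
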