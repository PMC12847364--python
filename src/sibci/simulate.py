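"""Synthetic EEG session generator with known ground-truth effect structure.

Signal model
------------
Linear instantaneous mixing of band-limited Gaussian sources with
task-gated variance, over a 1/f background:

    x(t) = sum_s  a_s * topo_s * gain_s(t) * s_s(t)  +  alpha + noise

Each imagery task is linked to one rhythmic source (a mu + beta pair of
band-limited Gaussian signals) whose scalp topography is a smooth kernel
over the 2-D projected 10-10 montage: lateralized central kernels for the
hand tasks, midline-central for feet, inferior-temporal for tongue and
inferior-frontal for the singing-imagery-specific source.  During a
trial's 4-s imagery window, the variance of the task's own source in
band b is scaled by ``1 + g * e_i * m_b`` where g is the global effect
size, ``e_i`` a per-trial multiplier and ``m_b`` the band's modulation
depth (negative = event-related desynchronization).  REST modulates
nothing — its signature is the *absence* of desynchronization.

Two knobs shape the task confusion structure: ``overlap_alpha`` mixes the
kinesthetic singing-imagery topography toward the tongue topography
(identical at 1.0), and ``sinokin_depth`` scales the non-kinesthetic
variant's modulation depth toward zero (REST-like at 0.0).

At ``g = 0`` every task-conditional distribution is identical by
construction, which makes the generator a leakage detector for the
downstream cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .config import ConfigError, ProtocolConfig, SimConfig
from .io import RawSession, make_events
from .montage import gaussian_topography, montage_2d
from .seeding import derive_seed
from .session import SessionPlan, make_session_plan

#: Simulation rhythm bands (Hz): the mu and beta ranges that carry the
#: task-gated modulation, and the task-independent posterior alpha.
MU_BAND = (8.0, 12.0)
BETA_BAND = (18.0, 26.0)
ALPHA_BAND = (8.0, 13.0)

#: Kernel centers per source (electrode names of the full 10-10 layout).
SOURCE_CENTERS: dict[str, list[str]] = {
    "hand_L": ["C4"],          # left-hand imagery -> right sensorimotor
    "hand_R": ["C3"],
    "feet": ["Cz"],
    "tongue": ["T7", "T8"],
    "si_unique": ["F7", "F8"],
}

#: Task -> (source, relative modulation depth).  REST drives no source.
TASK_SOURCE: dict[str, tuple[str, float]] = {
    "L": ("hand_L", 1.0),
    "R": ("hand_R", 1.0),
    "F": ("feet", 1.0),
    "T": ("tongue", 1.0),
    "SIkin": ("si_kin", 1.0),
    "SInoKin": ("si_nokin", None),  # depth filled from SimConfig.sinokin_depth
}

SELF_EVAL_CATEGORIES = ("correct", "not_correct", "correct_not_well")


def _bandlimited_noise(rng: np.random.Generator, band, fs, n, numtaps=501) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band`` Hz."""
    taps = sps.firwin(numtaps, band, pass_zero=False, fs=fs)
    x = sps.fftconvolve(rng.standard_normal(n + numtaps), taps, mode="same")[
        numtaps // 2 : numtaps // 2 + n
    ]
    return x / x.std()


def _pink_noise(rng: np.random.Generator, exponent, fs, n) -> np.ndarray:
    """Unit-variance 1/f^exponent (power) noise via spectral shaping."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1 / fs)
    shape = np.ones_like(f)
    mask = f > 0
    # Flatten below 1 Hz so the DC region does not dominate the variance.
    shape[mask] = np.maximum(f[mask], 1.0) ** (-exponent / 2)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n)
    return x / x.std()


def source_topographies(sim: SimConfig, names: list[str], xy: np.ndarray) -> dict[str, np.ndarray]:
    """Unit-peak scalp topography per source, including the SI mixtures."""
    topo = {
        s: gaussian_topography(centers, xy, names, sim.kernel_width)
        for s, centers in SOURCE_CENTERS.items()
    }
    mix = (1 - sim.overlap_alpha) * topo["si_unique"] + sim.overlap_alpha * topo["tongue"]
    topo["si_kin"] = mix / np.abs(mix).max()
    topo["si_nokin"] = topo["si_unique"]
    return topo


def simulate_raw(
    plan: SessionPlan,
    sim: SimConfig,
    cfg: ProtocolConfig,
    seed: int,
    trial_effect: np.ndarray | None = None,
    participant_id: str = "P01",
) -> RawSession:
    """Synthesize the continuous recording for a session plan.

    ``trial_effect`` (one multiplier per trial, default all ones) scales
    the effect size of individual trials; the informative self-evaluation
    mode uses it to degrade flagged trials.
    """
    unknown = set(plan.trials["task"]) - set(TASK_SOURCE) - {"REST"}
    if unknown:
        raise ConfigError(f"plan contains unknown task label(s): {sorted(unknown)}")
    n_trials = len(plan)
    if trial_effect is None:
        trial_effect = np.ones(n_trials)
    trial_effect = np.asarray(trial_effect, dtype=float)
    if trial_effect.shape != (n_trials,):
        raise ValueError("trial_effect must have one entry per trial")

    rng = np.random.default_rng(seed)
    names, xy = montage_2d(cfg.n_channels)
    topo = source_topographies(sim, names, xy)
    fs, n = plan.fs, plan.n_samples
    task_len = int(round(cfg.task_s * fs))
    g = sim.effect_size
    depth = {"mu": sim.mu_mod, "beta": sim.beta_mod}

    data = np.zeros((len(names), n))
    for source in ("hand_L", "hand_R", "feet", "tongue", "si_kin", "si_nokin"):
        for band_name, band in (("mu", MU_BAND), ("beta", BETA_BAND)):
            sig = _bandlimited_noise(rng, band, fs, n)
            gain = np.ones(n)
            for i, tr in enumerate(plan.trials.itertuples(index=False)):
                mapping = TASK_SOURCE.get(tr.task)
                if mapping is None or mapping[0] != source:
                    continue
                rel = mapping[1] if mapping[1] is not None else sim.sinokin_depth
                # Floor at near-total suppression: participant/trial
                # multipliers may push g*e*m below -1, but a variance
                # cannot go negative (ERD saturates at 100%).
                factor = max(1.0 + g * trial_effect[i] * rel * depth[band_name], 0.01)
                sl = slice(tr.onset_sample, min(tr.onset_sample + task_len, n))
                gain[sl] = np.sqrt(factor)
            data += sim.source_amp_uv * np.outer(topo[source], gain * sig)

    # Task-independent posterior alpha rhythm.
    alpha_topo = gaussian_topography(["Oz"], xy, names, sim.kernel_width)
    data += sim.alpha_amp_uv * np.outer(alpha_topo, _bandlimited_noise(rng, ALPHA_BAND, fs, n))

    # Independent 1/f background per channel.
    for ch in range(len(names)):
        data[ch] += sim.noise_amp_uv * _pink_noise(rng, sim.noise_exponent, fs, n)

    events = make_events(
        plan.trials["onset_sample"], plan.trials["code"], plan.trials["task"]
    )
    raw = RawSession(
        data=data,
        fs=fs,
        channel_names=names,
        events=events,
        participant_id=participant_id,
        provenance={"generator": "sibci.simulate", "seed": seed, "effect_size": g},
    )
    raw.validate()
    return raw


@dataclass
class SubjectiveData:
    """Per-participant questionnaire and per-trial self-evaluation data."""

    participant_id: str
    kviq_visual: int
    kviq_kinesthetic: int
    kviq_total: int
    #: rows = tasks, columns = assessed block numbers (1-based), values 1-5.
    difficulty: pd.DataFrame
    #: one category per trial, aligned with the session plan order.
    self_eval: pd.Series
    preferences: dict = field(default_factory=dict)

    def flagged(self, include_not_well: bool = False) -> np.ndarray:
        """Boolean mask of trials self-rated as badly performed."""
        bad = {"not_correct"} | ({"correct_not_well"} if include_not_well else set())
        return self.self_eval.isin(bad).to_numpy()

    def to_tsv(self, path) -> None:
        rows = [
            {"trial": i, "self_eval": v} for i, v in enumerate(self.self_eval)
        ]
        df = pd.DataFrame(rows)
        df.attrs = {}
        with open(path, "w") as fh:
            fh.write(f"# participant_id\t{self.participant_id}\n")
            fh.write(
                f"# kviq_visual\t{self.kviq_visual}\n# kviq_kinesthetic\t"
                f"{self.kviq_kinesthetic}\n# kviq_total\t{self.kviq_total}\n"
            )
            df.to_csv(fh, sep="\t", index=False)


# Baseline mean difficulty per task (5-point scale); REST is easiest and
# orofacial/singing tasks hardest, with practice lowering ratings over blocks.
_DIFFICULTY_BASE = {
    "L": 2.0, "R": 2.1, "F": 2.0, "T": 2.4, "SIkin": 2.5, "SInoKin": 2.0, "REST": 1.4,
}


def simulate_subjective(
    plan: SessionPlan,
    sim: SimConfig,
    seed: int,
    participant_effect: float = 1.0,
    participant_id: str = "P01",
) -> SubjectiveData:
    """Draw self-evaluation categories, difficulty ratings and KVIQ scores.

    The trial-wise categories are always drawn from ``self_eval_probs``;
    whether they are *causally linked* to signal quality is decided by the
    session-level orchestration (informative vs uninformative mode), not
    here.  KVIQ kinesthetic scores correlate with the participant's
    effect-size multiplier with strength ``kviq_effect_corr``.
    """
    p = np.asarray(sim.self_eval_probs, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ConfigError("self_eval_probs must sum to 1")
    rng = np.random.default_rng(seed)
    cats = rng.choice(len(p), size=len(plan), p=p)
    self_eval = pd.Series([SELF_EVAL_CATEGORIES[c] for c in cats], name="self_eval")

    n_blocks = plan.trials["block"].max() + 1
    assessed = sorted({1, (n_blocks + 1) // 2, n_blocks} if n_blocks >= 1 else set())
    tasks = [t for t in _DIFFICULTY_BASE if t in set(plan.trials["task"])]
    diff = {}
    for j, blk in enumerate(assessed):
        col = []
        for t in tasks:
            mean = _DIFFICULTY_BASE[t] - 0.1 * j  # mild practice effect
            col.append(int(np.clip(round(mean + rng.normal(0, 0.8)), 1, 5)))
        diff[blk] = col
    difficulty = pd.DataFrame(diff, index=tasks)

    # KVIQ-10: two 5-item subscales, 5-25 each.  The kinesthetic subscale is
    # tied to the participant's effect multiplier on a standardized scale.
    z_eff = np.log(max(participant_effect, 1e-6)) / max(sim.participant_sd, 1e-6)
    rho = sim.kviq_effect_corr
    z_kin = rho * z_eff + np.sqrt(max(1 - rho**2, 0)) * rng.standard_normal()
    kviq_kin = int(np.clip(round(15 + 4 * z_kin), 5, 25))
    kviq_vis = int(np.clip(round(17 + 3 * rng.standard_normal()), 5, 25))

    non_rest = [t for t in tasks if t != "REST"]
    top4 = list(rng.choice(non_rest, size=min(4, len(non_rest)), replace=False))
    preferences = {
        "top4": top4,
        "tongue_vs_si": "SI" if rng.random() < 13 / 14 else "T",
        "sikin_vs_sinokin": "SIkin" if rng.random() < 8 / 14 else "SInoKin",
    }
    return SubjectiveData(
        participant_id=participant_id,
        kviq_visual=kviq_vis,
        kviq_kinesthetic=kviq_kin,
        kviq_total=kviq_vis + kviq_kin,
        difficulty=difficulty,
        self_eval=self_eval,
        preferences=preferences,
    )


def trial_effect_from_self_eval(self_eval: pd.Series, sim: SimConfig) -> np.ndarray:
    """Per-trial effect multipliers implied by self-evaluation flags.

    Informative mode: not_correct and correct_not_well trials get the
    configured reduced multipliers (flags cause degraded signal).
    Uninformative mode: all ones (flags carry no signal information).
    """
    if sim.self_eval_mode == "uninformative":
        return np.ones(len(self_eval))
    mult = {
        "correct": 1.0,
        "not_correct": sim.flag_effect[0],
        "correct_not_well": sim.flag_effect[1],
    }
    return self_eval.map(mult).to_numpy(dtype=float)


def simulate_session(
    cfg: ProtocolConfig,
    sim: SimConfig,
    seed: int,
    participant_id: str = "P01",
    participant_effect: float = 1.0,
) -> tuple[RawSession, SubjectiveData, SessionPlan]:
    """Full session: plan -> subjective responses -> continuous EEG.

    The subjective draw happens first so that, in informative mode, the
    flagged trials can be synthesized with degraded (or zero) effect size.
    """
    plan = make_session_plan(cfg, derive_seed(seed, participant_id, "plan"))
    subjective = simulate_subjective(
        plan,
        sim,
        derive_seed(seed, participant_id, "subjective"),
        participant_effect=participant_effect,
        participant_id=participant_id,
    )
    trial_effect = participant_effect * trial_effect_from_self_eval(
        subjective.self_eval, sim
    )
    raw = simulate_raw(
        plan,
        sim,
        cfg,
        derive_seed(seed, participant_id, "raw"),
        trial_effect=trial_effect,
        participant_id=participant_id,
    )
    return raw, subjective, plan


def draw_participant_effects(
    sim: SimConfig, n_participants: int, seed: int
) -> np.ndarray:
    """Lognormal per-participant multipliers on the global effect size."""
    rng = np.random.default_rng(derive_seed(seed, "participants"))
    return np.exp(rng.normal(0.0, sim.participant_sd, size=n_participants))
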