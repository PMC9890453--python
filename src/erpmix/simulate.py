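"""Single-trial ERP simulator for the all-or-none vs. graded question.

Two generative hypotheses for the face-specific N170 are implemented:

* ``all_or_none`` — on each intact-face trial a Bernoulli detection draw
  gates a *full* face-specific response: the N170 increment is either
  ``a_n170_full`` (detected) or 0 (missed).  Averaging across trials then
  dilutes the apparent amplitude by the detection probability — the
  signal-averaging artifact the analysis chain is designed to expose.
* ``graded`` — the face-specific increment scales deterministically with a
  duration-dependent gain ``g(duration) in (0, 1]``, so every trial carries a
  partial response and no amount of conditioning on confidence removes the
  duration effect.

Each trial's epoch is the sum of a positive P1 Gaussian template, a negative
N1/N170 Gaussian template scaled by the trial's component amplitude, and
white Gaussian noise.  The N1/N170 complex on a trial is

    amp_n1 = base(type) + half2_gain*[intact, half 2] + eff_amp_n170
             + u_participant + u_stimulus + trial jitter

with ``eff_amp_n170`` the face-specific part described above (magnitude
conventions: amplitudes are stored as positive magnitudes and rendered with
the component's polarity).

Confidence keys come from a single signed latent evidence variable
(face-positive) cut by two symmetric thresholds; see :func:`assign_responses`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .design import DURATION_LONG, DURATION_SHORT

# Posterior lateral clusters centred on PO7 (left) and PO8 (right), in the
# 128-channel geodesic labelling.
LEFT_CLUSTER = ["E65", "E70", "E66", "E59", "E58", "E64", "E69"]
RIGHT_CLUSTER = ["E90", "E96", "E91", "E84", "E83", "E89", "E95"]


@dataclass
class GenerativeParams:
    """Full parameterization of the simulator.

    Amplitudes are magnitudes in microvolts; times in ms; the epoch grid is
    ``epoch_start..epoch_end`` sampled at ``sample_rate`` Hz.
    """

    hypothesis: str = "all_or_none"

    # component amplitudes (uV magnitudes)
    a_n170_full: float = 4.0    # full face-specific N170 increment
    a_n1_base: float = 2.0      # nonspecific N1 for intact stimuli
    a_n1_scrambled: float = 1.2  # nonspecific N1 for scrambled stimuli
    a_p1: float = 3.0
    half2_gain: float = 0.8     # nonspecific N1 increment in half 2 (intact)
    right_gain: float = 1.15    # right-hemisphere N1/N170 scaling

    # detection probabilities per (category, duration) — all_or_none only
    p_detect: dict = field(
        default_factory=lambda: {
            ("face", DURATION_SHORT): 0.475,
            ("face", DURATION_LONG): 0.99,
            ("house", DURATION_SHORT): 0.18,
            ("house", DURATION_LONG): 0.98,
        }
    )
    # graded gain per duration — graded only; g(216) = 1
    g: dict = field(
        default_factory=lambda: {DURATION_SHORT: 1.0, DURATION_LONG: 1.0}
    )

    # random effects and noise (uV)
    sd_participant: float = 1.0
    sd_stimulus: float = 0.5
    sd_amp: float = 1.0         # trial-level N1-complex jitter
    sd_noise: float = 10.0      # white epoch noise per channel and sample

    # Gaussian component templates (ms)
    n170_center: float = 172.0
    n170_sd: float = 16.5
    p1_center: float = 116.0
    p1_sd: float = 16.5

    # latent-evidence confidence model
    mu_evidence: float = 4.0
    sd_evidence: float = 1.0
    sd_evidence_undetected: float = 0.8
    sd_evidence_scrambled: float = 0.5
    thresh_guess: float = 0.6
    thresh_sure: float = 1.8

    sample_rate: float = 250.0
    epoch_start: float = -500.0
    epoch_end: float = 996.0

    def __post_init__(self) -> None:
        if self.hypothesis not in ("all_or_none", "graded"):
            raise ValueError(f"unknown hypothesis {self.hypothesis!r}")
        for k, p in self.p_detect.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p_detect{k} = {p} outside [0, 1]")
        if not 0.0 < self.g[DURATION_SHORT] <= self.g[DURATION_LONG] == 1.0:
            raise ValueError("require 0 < g(33) <= g(216) = 1")
        for name in ("sd_participant", "sd_stimulus", "sd_amp", "sd_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    # -- presets -------------------------------------------------------
    @classmethod
    def all_or_none_preset(cls, **kw) -> "GenerativeParams":
        """Calibrated all-or-none preset (Key-1 share ~= 0.47 at 33 ms)."""
        return cls(hypothesis="all_or_none", **kw)

    @classmethod
    def graded_preset(cls, **kw) -> "GenerativeParams":
        """Graded preset, behaviourally matched to the all-or-none one.

        g(33) = 0.43 puts the mean 33 ms evidence at the sure threshold, so
        the Key-1 share matches the all-or-none preset while the neural
        response is scaled on every trial.
        """
        kw.setdefault("g", {DURATION_SHORT: 0.43, DURATION_LONG: 1.0})
        return cls(hypothesis="graded", **kw)

    # -- (de)serialisation --------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["p_detect"] = {f"{c}:{dur}": v for (c, dur), v in self.p_detect.items()}
        d["g"] = {str(k): v for k, v in self.g.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GenerativeParams":
        d = dict(d)
        if "p_detect" in d:
            d["p_detect"] = {
                (k.split(":")[0], int(k.split(":")[1])): v
                for k, v in d["p_detect"].items()
            }
        if "g" in d:
            d["g"] = {int(k): v for k, v in d["g"].items()}
        return cls(**d)

    def times(self) -> np.ndarray:
        step = 1000.0 / self.sample_rate
        n = int(round((self.epoch_end - self.epoch_start) / step)) + 1
        return self.epoch_start + step * np.arange(n)


def simulate_trials(
    design: pd.DataFrame, params: GenerativeParams, seed: int
) -> pd.DataFrame:
    """Draw latent states, component amplitudes and responses per trial.

    The detection uniforms and evidence normals are drawn in the same order
    under both hypotheses, so graded with g = 1 reproduces all_or_none with
    p_detect = 1 bit-for-bit at the same seed.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    rng_re, rng_lat, rng_key = (np.random.default_rng(s) for s in ss)

    trials = design.copy().reset_index(drop=True)
    n = len(trials)
    if n == 0:
        raise ValueError("empty design")

    participants = np.sort(trials["participant_id"].unique())
    stimuli = np.sort(trials["stimulus_id"].unique())
    u_p = dict(zip(participants, rng_re.normal(0, params.sd_participant, len(participants))))
    u_s = dict(zip(stimuli, rng_re.normal(0, params.sd_stimulus, len(stimuli))))

    intact = (trials["type"] == "intact").to_numpy()
    face = (trials["category"] == "face").to_numpy()
    dur = trials["duration"].to_numpy()
    half2 = (trials["half"] == 2).to_numpy()

    det_u = rng_lat.uniform(size=n)
    ev_z = rng_lat.normal(size=n)

    p_det = np.array(
        [
            params.p_detect[(c, d)] if t == "intact" else 0.0
            for c, d, t in zip(trials["category"], dur, trials["type"])
        ]
    )
    if params.hypothesis == "all_or_none":
        detected = (det_u < p_det) & intact
        gain = np.ones(n)
        eff = np.where(face & intact & detected, params.a_n170_full, 0.0)
        ev_loc = np.where(detected, params.mu_evidence, 0.0)
        ev_sd = np.where(
            detected,
            params.sd_evidence,
            np.where(intact, params.sd_evidence_undetected, params.sd_evidence_scrambled),
        )
    else:  # graded
        detected = intact  # no discrete gate; kept for schema compatibility
        gain = np.array([params.g[d] for d in dur])
        eff = np.where(face & intact, gain * params.a_n170_full, 0.0)
        ev_loc = np.where(intact, gain * params.mu_evidence, 0.0)
        ev_sd = np.where(intact, params.sd_evidence, params.sd_evidence_scrambled)

    sign = np.where(face, 1.0, -1.0)
    evidence = sign * ev_loc + ev_sd * ev_z

    base = np.where(intact, params.a_n1_base, params.a_n1_scrambled)
    jitter = rng_key.normal(0, params.sd_amp, n)
    amp_n1 = (
        base
        + params.half2_gain * (half2 & intact)
        + eff
        + np.array([u_p[p] for p in trials["participant_id"]])
        + np.array([u_s[s] for s in trials["stimulus_id"]])
        + jitter
    )

    trials["detected"] = detected.astype(int)
    trials["gain"] = gain
    trials["evidence"] = evidence
    trials["eff_amp_n170"] = eff
    trials["amp_n1"] = amp_n1
    trials["amp_p1"] = params.a_p1
    trials["response_key"] = assign_responses(
        evidence, params.thresh_guess, params.thresh_sure
    )
    return trials


def assign_responses(
    evidence: np.ndarray, thresh_guess: float, thresh_sure: float
) -> np.ndarray:
    """Map signed (face-positive) evidence to confidence Keys 1-5.

    Key 1: sure face (e > thresh_sure); Key 2: unsure face; Key 3: no idea
    (|e| <= thresh_guess); Key 4: unsure house; Key 5: sure house.  Thresholds
    must satisfy 0 <= thresh_guess < thresh_sure (infinite thresholds send
    every trial to Key 3).
    """
    both_inf = np.isinf(thresh_guess) and np.isinf(thresh_sure)
    if not (0 <= thresh_guess < thresh_sure or (both_inf and thresh_guess > 0)):
        raise ValueError(
            f"non-monotone thresholds: guess={thresh_guess}, sure={thresh_sure}"
        )
    e = np.asarray(evidence, dtype=float)
    keys = np.full(e.shape, 3, dtype=int)
    keys[e > thresh_guess] = 2
    keys[e > thresh_sure] = 1
    keys[e < -thresh_guess] = 4
    keys[e < -thresh_sure] = 5
    return keys


@dataclass
class EpochSet:
    """Trials x channels x samples amplitude array (uV) with metadata."""

    data: np.ndarray
    times: np.ndarray  # ms
    channels: list
    hemisphere: dict  # channel label -> "left" | "right"
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.metadata):
            raise ValueError("metadata row count must equal trial count")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel label count must match data")
        if self.data.shape[2] != len(self.times):
            raise ValueError("time grid must match data")

    def copy(self) -> "EpochSet":
        return EpochSet(
            self.data.copy(),
            self.times.copy(),
            list(self.channels),
            dict(self.hemisphere),
            self.metadata.copy(),
        )

    def channel_indices(self, labels) -> np.ndarray:
        idx = []
        for lab in labels:
            if lab not in self.channels:
                raise KeyError(f"unknown channel label {lab!r}")
            idx.append(self.channels.index(lab))
        return np.array(idx)

    def sample_index(self, t_ms: float) -> int:
        """Nearest-sample index for a time in ms."""
        return int(np.argmin(np.abs(self.times - t_ms)))

    # -- flat-binary + JSON sidecar interchange -----------------------
    def save(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.save(d / "epochs.npy", self.data)
        self.metadata.to_csv(d / "metadata.tsv", sep="\t", index=False)
        sidecar = {
            "times_ms": self.times.tolist(),
            "channels": list(self.channels),
            "hemisphere": self.hemisphere,
            "metadata": "metadata.tsv",
        }
        (d / "epochs.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, directory) -> "EpochSet":
        from pathlib import Path

        d = Path(directory)
        sidecar = json.loads((d / "epochs.json").read_text())
        return cls(
            data=np.load(d / "epochs.npy"),
            times=np.asarray(sidecar["times_ms"], dtype=float),
            channels=list(sidecar["channels"]),
            hemisphere=dict(sidecar["hemisphere"]),
            metadata=pd.read_csv(d / sidecar["metadata"], sep="\t"),
        )


def gaussian_template(times: np.ndarray, center: float, sd: float) -> np.ndarray:
    """Unit-peak Gaussian bump on the epoch time grid."""
    return np.exp(-0.5 * ((times - center) / sd) ** 2)


def template_window_mean(
    center: float, sd: float, start: float, end: float, sample_rate: float = 250.0
) -> float:
    """Mean of the unit Gaussian template over the sample grid in [start, end]."""
    step = 1000.0 / sample_rate
    # grid aligned with the epoch grid (multiples of the sample step)
    lo = int(np.ceil(start / step - 1e-9))
    hi = int(np.floor(end / step + 1e-9))
    t = step * np.arange(lo, hi + 1)
    return float(gaussian_template(t, center, sd).mean())


def render_epochs(
    trials: pd.DataFrame,
    params: GenerativeParams,
    seed: int,
    left_cluster: list | None = None,
    right_cluster: list | None = None,
) -> EpochSet:
    """Render one epoch per trial on the posterior cluster channels.

    Every channel of a cluster carries the same signal (scaled by the
    hemisphere gain for the N1/N170) plus independent white noise, so
    averaging the cluster reduces noise as 1/sqrt(n_channels) without
    changing the mean — the property single-trial window means rely on.
    """
    if len(trials) == 0:
        raise ValueError("trial list is empty")
    left = LEFT_CLUSTER if left_cluster is None else list(left_cluster)
    right = RIGHT_CLUSTER if right_cluster is None else list(right_cluster)
    channels = left + right
    hemisphere = {c: "left" for c in left} | {c: "right" for c in right}

    times = params.times()
    for name, center, sd in (
        ("N170", params.n170_center, params.n170_sd),
        ("P1", params.p1_center, params.p1_sd),
    ):
        if center - 4 * sd < times[0] or center + 4 * sd > times[-1]:
            raise ValueError(
                f"{name} template support [{center - 4 * sd}, {center + 4 * sd}] "
                f"exceeds the epoch span"
            )

    n1_t = gaussian_template(times, params.n170_center, params.n170_sd)
    p1_t = gaussian_template(times, params.p1_center, params.p1_sd)

    amp_n1 = trials["amp_n1"].to_numpy()[:, None]
    amp_p1 = trials["amp_p1"].to_numpy()[:, None]
    hemi_gain = np.array(
        [1.0 if hemisphere[c] == "left" else params.right_gain for c in channels]
    )

    # signal per trial x sample, then broadcast over channels with the
    # hemisphere gain applied to the negative-going N1/N170 only
    p1_part = amp_p1 * p1_t[None, :]
    n1_part = amp_n1 * n1_t[None, :]
    data = (
        p1_part[:, None, :]
        - hemi_gain[None, :, None] * n1_part[:, None, :]
    )
    if params.sd_noise > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
        data = data + rng.normal(0.0, params.sd_noise, size=data.shape)

    return EpochSet(
        data=data,
        times=times,
        channels=channels,
        hemisphere=hemisphere,
        metadata=trials.reset_index(drop=True),
    )
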