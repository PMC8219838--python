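"""Synthetic LGN: linear-nonlinear-Poisson neurons with delayed surrounds.

The generator produces magno- and parvocellular model neurons whose
temporal tuning arises from center-surround antagonism in time.  The
stimulus is spatially uniform within the receptive field, so center and
surround are purely temporal channels: both share one gamma kernel, and
the surround is delayed by ``delta`` relative to the center.  For a
magnocellular cell (non-opponent center and surround, both summing L
and M), the delayed subtraction cancels slow L+M modulations and passes
faster ones -- bandpass luminance tuning.  For a parvocellular cell
(single-cone center, mixed surround), an L-M modulation drives center
excitation and surround disinhibition nearly together at low
frequencies and in opposition at high frequencies -- low-pass chromatic
tuning.  Firing is an inhomogeneous Poisson process on the rectified
drive.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from lgnsnr.snr import MissingBaselineError, Trial, TrialSet
from lgnsnr.stimuli import StimulusSpec, cone_contrast_waveforms

__all__ = [
    "LNPNeuron",
    "CLASS_DEFAULTS",
    "make_neuron",
    "drive",
    "sample_spikes",
    "generate_experiment",
]


@dataclass(frozen=True)
class LNPNeuron:
    """Generative model of one LGN neuron.

    Cone weights are scalars on the L/M contrast waveforms for the
    center (``w_lc, w_mc``) and surround (``w_ls, w_ms``).  The shared
    temporal kernel is a unit-area gamma filter (``tau_c`` seconds,
    ``n_c`` stages); the surround path applies the same kernel delayed
    by ``delta``.  ``gain`` converts filtered contrast drive to
    spikes/s; ``baseline_rate`` is the spontaneous rate; ``latency``
    shifts the whole response.
    """

    cell_class: str  # "magno" or "parvo"
    w_lc: float
    w_mc: float
    w_ls: float
    w_ms: float
    tau_c: float = 0.012
    n_c: int = 3
    delta: float = 0.010
    baseline_rate: float = 30.0
    gain: float = 400.0
    latency: float = 0.100
    eccentricity: float = 5.0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline rate must be nonnegative")
        if self.delta <= 0:
            raise ValueError("surround delay must be positive")


# Class-conditional defaults. Gains and baselines are calibration
# choices that put population-level d' in the physiological range
# (order 1-10 at behavioral-threshold contrasts).
CLASS_DEFAULTS: dict[str, dict] = {
    "magno": dict(
        # non-opponent center and near-balancing non-opponent surround:
        # the 10 ms surround delay then nulls slow L+M drive almost
        # completely, producing the bandpass luminance tuning
        w_lc=1.0,
        w_mc=1.0,
        w_ls=0.98,
        w_ms=0.98,
        tau_c=0.008,
        baseline_rate=40.0,
        gain=400.0,
        latency=0.090,
    ),
    "parvo": dict(
        # center is a single cone (L or M, chosen per neuron); the
        # surround draws on both cone types and cancels out of the L-M
        # response, leaving low-pass chromatic tuning set by the kernel
        w_lc=1.0,
        w_mc=0.0,
        w_ls=0.45,
        w_ms=0.45,
        tau_c=0.012,
        baseline_rate=20.0,
        gain=380.0,
        latency=0.110,
    ),
}


def make_neuron(
    cell_class: str,
    eccentricity: float = 5.0,
    seed: int | np.random.Generator = 0,
    jitter: float = 0.15,
) -> LNPNeuron:
    """Draw one neuron around its class defaults.

    Baseline rate, gain and latency get multiplicative lognormal jitter
    of SD ``jitter`` (in log units); the cone-weight structure that
    defines the class is preserved exactly: magnocellular neurons keep
    ``w_lc == w_mc`` (non-opponent), parvocellular neurons keep exactly
    one nonzero center weight (L- or M-center with equal probability).
    Deterministic given ``seed``.
    """
    if cell_class not in CLASS_DEFAULTS:
        raise ValueError(f"unknown cell class {cell_class!r}")
    rng = np.random.default_rng(seed)
    p = dict(CLASS_DEFAULTS[cell_class])
    for key in ("baseline_rate", "gain"):
        p[key] = p[key] * float(np.exp(rng.normal(0.0, jitter)))
    p["latency"] = p["latency"] * float(np.exp(rng.normal(0.0, jitter / 3)))
    if cell_class == "parvo" and rng.random() < 0.5:
        p["w_lc"], p["w_mc"] = p["w_mc"], p["w_lc"]  # M-center cell
    return LNPNeuron(cell_class=cell_class, eccentricity=eccentricity, **p)


def _gamma_kernel(t: np.ndarray, tau: float, n: int) -> np.ndarray:
    from scipy.special import gamma as gamma_fn

    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = (tp / tau) ** (n - 1) * np.exp(-tp / tau) / (tau * gamma_fn(n))
    return out


def _shift(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Delay a causal signal by ``n_bins`` samples, zero-padding the front."""
    if n_bins <= 0:
        return x
    out = np.zeros_like(x)
    out[n_bins:] = x[: len(x) - n_bins]
    return out


def drive(
    neuron: LNPNeuron,
    c_l: np.ndarray,
    c_m: np.ndarray,
    dt: float,
) -> np.ndarray:
    """Instantaneous firing rate (spikes/s) of the neuron.

    ``rate(t) = max(0, r0 + g * [center drive](t - latency)
                         - g * [surround drive](t - latency - delta))``

    where center/surround drives are the cone-weighted contrast sums
    convolved with the shared gamma kernel, and the surround is further
    delayed by ``delta``.  Inputs must be equal-length uniform samples.
    """
    c_l = np.asarray(c_l, dtype=float)
    c_m = np.asarray(c_m, dtype=float)
    if c_l.shape != c_m.shape:
        raise ValueError("c_l and c_m must have identical shapes")
    t_kern = np.arange(0.0, 12 * neuron.tau_c * neuron.n_c, dt)
    kern = _gamma_kernel(t_kern, neuron.tau_c, neuron.n_c)
    center_in = neuron.w_lc * c_l + neuron.w_mc * c_m
    surround_in = neuron.w_ls * c_l + neuron.w_ms * c_m
    center = np.convolve(center_in, kern)[: len(c_l)] * dt
    surround = np.convolve(surround_in, kern)[: len(c_l)] * dt
    lat_bins = int(round(neuron.latency / dt))
    delta_bins = int(round(neuron.delta / dt))
    rate = (
        neuron.baseline_rate
        + neuron.gain * _shift(center, lat_bins)
        - neuron.gain * _shift(surround, lat_bins + delta_bins)
    )
    return np.maximum(rate, 0.0)


def sample_spikes(
    rate: np.ndarray,
    dt: float,
    n_trials: int,
    seed: int | np.random.Generator = 0,
) -> list[np.ndarray]:
    """Independent inhomogeneous-Poisson spike trains from ``rate(t)``.

    Per-bin Poisson counts with mean ``rate * dt``, spike times placed
    uniformly within their bin.  Deterministic given ``seed``.
    """
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise ValueError("rate must be nonnegative")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rate * dt, size=(n_trials, len(rate)))
    trials = []
    bin_starts = np.arange(len(rate)) * dt
    for i in range(n_trials):
        idx = np.repeat(np.arange(len(rate)), counts[i])
        times = bin_starts[idx] + rng.random(len(idx)) * dt
        trials.append(np.sort(times))
    return trials


def generate_experiment(
    neurons: list[LNPNeuron],
    schedule: dict[str, StimulusSpec],
    n_trials_per_condition: int,
    seed: int = 0,
    dt: float = 0.001,
    epoch_pad: float = 0.35,
) -> list[TrialSet]:
    """Simulate a full experiment: one TrialSet per neuron.

    ``schedule`` maps condition_id -> StimulusSpec and must include a
    blank.  The simulated epoch extends ``epoch_pad`` seconds past
    stimulus offset so that latency-delayed counting windows remain
    fully inside the recorded data.  Seeding uses a spawned seed
    sequence per (neuron, condition), so results are reproducible and
    independent across cells and conditions.
    """
    if not any(spec.is_blank for spec in schedule.values()):
        raise MissingBaselineError("schedule must include a blank condition")
    root = np.random.SeedSequence(seed)
    neuron_seqs = root.spawn(len(neurons))
    out: list[TrialSet] = []
    cond_ids = sorted(schedule)
    durations = {schedule[c].duration for c in cond_ids}
    if len(durations) != 1:
        raise ValueError("all conditions in a schedule must share one duration")
    duration = durations.pop()
    for neuron, nseq in zip(neurons, neuron_seqs):
        cond_seqs = nseq.spawn(len(cond_ids))
        trials: list[Trial] = []
        trial_id = 0
        for cid, cseq in zip(cond_ids, cond_seqs):
            spec = schedule[cid]
            c_l, c_m = cone_contrast_waveforms(spec, dt)
            n_pad = int(round(epoch_pad / dt))
            c_l = np.concatenate([c_l, np.zeros(n_pad)])
            c_m = np.concatenate([c_m, np.zeros(n_pad)])
            rate = drive(neuron, c_l, c_m, dt)
            spike_trains = sample_spikes(
                rate, dt, n_trials_per_condition, np.random.default_rng(cseq)
            )
            for st in spike_trains:
                trials.append(Trial(trial_id=trial_id, condition_id=cid, spike_times=st))
                trial_id += 1
        out.append(
            TrialSet(trials=trials, conditions=dict(schedule), stim_on=0.0, stim_off=duration)
        )
    return out


def scale_gain(neuron: LNPNeuron, factor: float) -> LNPNeuron:
    """Copy of ``neuron`` with contrast gain scaled by ``factor``."""
    return replace(neuron, gain=neuron.gain * factor)
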