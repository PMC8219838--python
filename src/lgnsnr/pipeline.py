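"""Orchestration of the cones -> LGN -> behavior comparison.

``run_experiment`` drives the whole analysis from one config: build the
threshold-equated stimulus schedule, simulate (or read) LGN spike
trains, estimate per-neuron F1 d' against blanks, inflate to population
d' with correlated pooling, compute the cone-array matched-filter bound
for every condition, and tabulate the cross-stage SNR gaps against the
behavioral criterion d'.  All randomness flows from one master seed
through spawned seed sequences, so identical config + seed reproduces
identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from lgnsnr import io as lgn_io
from lgnsnr.cones import ConeMosaicModel, cone_array_dprime, snr_gap
from lgnsnr.lgn import LNPNeuron, generate_experiment, make_neuron
from lgnsnr.population import (
    CellClassParams,
    PopulationModel,
    effective_neuron_count,
    population_dprime,
)
from lgnsnr.snr import CountingWindow, TrialSet, bootstrap_se, dprime_f1
from lgnsnr.stimuli import (
    ColorDirection,
    StimulusSpec,
    TCSFModel,
    pc_to_dprime,
    threshold_contrast,
)

__all__ = [
    "ExperimentConfig",
    "threshold_schedule",
    "run_experiment",
]

logger = logging.getLogger("lgnsnr")


@dataclass
class ExperimentConfig:
    """Everything needed to run the cross-stage comparison.

    Defaults emulate the study conditions: near-threshold L+M and L-M
    drifting Gabors at 1-20 Hz with 166 ms trapezoidal ramps, presented
    at 5 degrees eccentricity, recorded against a blank baseline.
    """

    frequencies_hz: list[float] = field(
        default_factory=lambda: [1.0, 2.0, 5.0, 10.0, 20.0]
    )
    directions: list[str] = field(default_factory=lambda: ["L+M", "L-M"])
    duration_s: float = 1.0
    ramp_s: float = 0.166
    eccentricity_deg: float = 5.0
    aperture_sigma_deg: float = 0.4
    n_neurons_per_class: int = 12
    n_trials_per_condition: int = 100
    threshold_pc: float = 0.82
    window_start_offset_s: float = 0.0
    window_end_offset_s: float = 0.0
    dt_s: float = 0.001
    n_bootstrap: int = 500
    tcsf: TCSFModel = field(default_factory=TCSFModel)
    population: PopulationModel = field(default_factory=PopulationModel)
    cones: ConeMosaicModel = field(default_factory=ConeMosaicModel)

    @property
    def criterion_dprime(self) -> float:
        """Behavioral criterion d' implied by percent correct at threshold."""
        return pc_to_dprime(self.threshold_pc)

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tcsf"] = {
            "eccentricity_slope": self.tcsf.eccentricity_slope,
            "reference_eccentricity": self.tcsf.reference_eccentricity,
            "params": {
                dir_.value: dataclasses.asdict(p)
                for dir_, p in self.tcsf.params.items()
            },
        }
        d["population"] = {
            cls: dataclasses.asdict(p) for cls, p in self.population.classes.items()
        }
        d["cones"] = dataclasses.asdict(self.cones)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        from lgnsnr.stimuli import TCSFFilterParams

        d = dict(d)
        if "tcsf" in d and isinstance(d["tcsf"], dict):
            t = d["tcsf"]
            params = {
                ColorDirection.parse(k): TCSFFilterParams(**v)
                for k, v in t.get("params", {}).items()
            }
            kwargs = {}
            if params:
                kwargs["params"] = params
            for key in ("eccentricity_slope", "reference_eccentricity"):
                if key in t:
                    kwargs[key] = t[key]
            d["tcsf"] = TCSFModel(**kwargs)
        if "population" in d and isinstance(d["population"], dict):
            d["population"] = PopulationModel(
                classes={k: CellClassParams(**v) for k, v in d["population"].items()}
            )
        if "cones" in d and isinstance(d["cones"], dict):
            d["cones"] = ConeMosaicModel(**d["cones"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def threshold_schedule(
    config: ExperimentConfig,
) -> tuple[dict[str, StimulusSpec], dict[str, bool]]:
    """Stimulus schedule with every condition at behavioral threshold.

    Returns (condition_id -> spec, condition_id -> gamut-clipped flag);
    always includes the blank condition.
    """
    schedule: dict[str, StimulusSpec] = {}
    clipped: dict[str, bool] = {}
    for direction in self_directions(config):
        for f in config.frequencies_hz:
            thr = threshold_contrast(
                config.tcsf, direction, f, config.eccentricity_deg
            )
            cid = f"{direction.value}_{f:g}Hz"
            schedule[cid] = StimulusSpec(
                color_direction=direction,
                temporal_frequency=f,
                cone_contrast=thr.contrast,
                duration=config.duration_s,
                ramp=config.ramp_s,
                eccentricity=config.eccentricity_deg,
                aperture_sigma=config.aperture_sigma_deg,
            )
            clipped[cid] = thr.clipped
            if thr.clipped:
                logger.warning(
                    "condition %s: threshold contrast clipped to gamut cap %.3g",
                    cid,
                    thr.contrast,
                )
    schedule["blank"] = StimulusSpec(
        color_direction=ColorDirection.BLANK,
        duration=config.duration_s,
        ramp=config.ramp_s,
        eccentricity=config.eccentricity_deg,
        aperture_sigma=config.aperture_sigma_deg,
    )
    clipped["blank"] = False
    return schedule, clipped


def self_directions(config: ExperimentConfig) -> list[ColorDirection]:
    return [ColorDirection.parse(d) for d in config.directions]


def simulate_lgn(
    config: ExperimentConfig,
    schedule: dict[str, StimulusSpec],
    seed: int,
) -> dict[str, list[tuple[LNPNeuron, TrialSet]]]:
    """Simulate trial sets for both cell classes from the config."""
    root = np.random.SeedSequence(seed)
    class_seqs = dict(zip(("magno", "parvo"), root.spawn(2)))
    out: dict[str, list[tuple[LNPNeuron, TrialSet]]] = {}
    for cls, seq in class_seqs.items():
        neuron_seed_seq, exp_seed_seq = seq.spawn(2)
        neuron_rng = np.random.default_rng(neuron_seed_seq)
        neurons = [
            make_neuron(cls, config.eccentricity_deg, neuron_rng)
            for _ in range(config.n_neurons_per_class)
        ]
        exp_seed = int(exp_seed_seq.generate_state(1)[0] % (2**31))
        trial_sets = generate_experiment(
            neurons,
            schedule,
            config.n_trials_per_condition,
            seed=exp_seed,
            dt=config.dt_s,
        )
        out[cls] = list(zip(neurons, trial_sets))
        logger.info("simulated %d %s neurons x %d conditions", len(neurons), cls, len(schedule))
    return out


def per_neuron_dprime_table(
    config: ExperimentConfig,
    sims: dict[str, list[tuple[LNPNeuron, TrialSet]]],
    schedule: dict[str, StimulusSpec],
    seed: int = 0,
    with_se: bool = False,
) -> pd.DataFrame:
    """F1 d' per neuron and condition at the configured counting window."""
    window = CountingWindow(
        0.0 + config.window_start_offset_s,
        config.duration_s + config.window_end_offset_s,
    )
    rows = []
    for cls, pairs in sims.items():
        for idx, (neuron, ts) in enumerate(pairs):
            for cid, spec in schedule.items():
                if spec.is_blank:
                    continue
                est = dprime_f1(ts, cid, window)
                se = (
                    bootstrap_se(ts, cid, window, config.n_bootstrap, seed=seed)
                    if with_se
                    else float("nan")
                )
                rows.append(
                    {
                        "cell_class": cls,
                        "neuron": idx,
                        "condition_id": cid,
                        "direction": spec.color_direction.value,
                        "frequency_hz": spec.temporal_frequency,
                        "dprime": est.dprime,
                        "se": se,
                        "window_start_s": window.start,
                        "window_end_s": window.end,
                    }
                )
    return pd.DataFrame(rows)


def run_experiment(
    config: ExperimentConfig,
    seed: int = 0,
    outdir: str | Path | None = None,
    write_rasters: bool = False,
) -> pd.DataFrame:
    """Run the full cross-stage comparison; returns the stage table.

    One row per stimulus condition with behavioral criterion d', magno
    and parvo population d' (mean across neurons, scaled by the pooling
    factor) with SEs, the cone-array d' bound, and the cone->LGN and
    LGN->behavior gaps per class (unphysical violations flagged, never
    clamped).
    """
    schedule, clipped = threshold_schedule(config)
    sims = simulate_lgn(config, schedule, seed)
    neuron_table = per_neuron_dprime_table(config, sims, schedule, seed=seed)

    criterion = config.criterion_dprime
    rows = []
    for cid in sorted(c for c in schedule if not schedule[c].is_blank):
        spec = schedule[cid]
        row: dict = {
            "condition_id": cid,
            "direction": spec.color_direction.value,
            "frequency_hz": spec.temporal_frequency,
            "contrast": spec.cone_contrast,
            "gamut_clipped": clipped[cid],
            "behavior_dprime": criterion,
        }
        cone_d = cone_array_dprime(spec, config.cones)
        row["cone_dprime"] = cone_d
        for cls in sims:
            sub = neuron_table[
                (neuron_table.cell_class == cls) & (neuron_table.condition_id == cid)
            ]
            d_single = float(sub.dprime.mean())
            sem_single = float(sub.dprime.std(ddof=1) / np.sqrt(len(sub)))
            n_eff = effective_neuron_count(config.population, spec, cls)
            rho = config.population[cls].rho
            d_pop, k = population_dprime(d_single, max(n_eff, 1.0), rho)
            gap = snr_gap(cone_d, max(d_pop, 0.0))
            row.update(
                {
                    f"{cls}_dprime_single": d_single,
                    f"{cls}_n_eff": n_eff,
                    f"{cls}_scale_factor": k,
                    f"{cls}_dprime_population": d_pop,
                    f"{cls}_se_population": k * sem_single,
                    f"cone_minus_{cls}": gap.difference,
                    f"transmitted_fraction_{cls}": gap.fraction,
                    f"unphysical_{cls}": gap.unphysical,
                    f"{cls}_minus_behavior": d_pop - criterion,
                }
            )
            if gap.unphysical:
                logger.warning("condition %s: %s population d' exceeds cone bound", cid, cls)
        rows.append(row)
    stage = pd.DataFrame(rows).sort_values(["direction", "frequency_hz"]).reset_index(
        drop=True
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        lgn_io.write_conditions(outdir / "conditions.tsv", schedule, clipped)
        neuron_table.to_csv(outdir / "per_neuron_dprime.tsv", sep="\t", index=False)
        stage.to_csv(outdir / "stage_comparison.tsv", sep="\t", index=False)
        if write_rasters:
            for cls, pairs in sims.items():
                for idx, (_, ts) in enumerate(pairs):
                    lgn_io.write_rasters(outdir / f"rasters_{cls}_{idx:02d}.tsv", ts)
        meta = {
            "config_hash": config.config_hash(),
            "seed": seed,
            "version": __import__("lgnsnr").__version__,
            "criterion_dprime": criterion,
            "cone_light_level_mismatch": config.cones.light_level_mismatch(),
        }
        (outdir / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return stage
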