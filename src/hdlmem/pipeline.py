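"""Configuration-driven experiment orchestration.

A :class:`RunConfig` names an experiment type, a seed, and the generator
and analysis parameters; :func:`run_experiment` executes the matching
generator -> analysis -> statistics chain, compares the recovered values to
the recorded ground truth, and (optionally) serializes the whole bundle to
an output directory.  Reruns with the same config are bit-reproducible.
"""

from __future__ import annotations

import copy
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import fcs, laurdan, partition, spt, stats, synthetic

log = logging.getLogger("hdlmem")

__all__ = ["RunConfig", "run_experiment", "PACKAGED_CONFIGS"]

_KNOWN_EXPERIMENTS = (
    "fcs_pre_post",
    "kp_spots",
    "kp_intensity",
    "spt_mixture",
    "gp_recovery",
)


@dataclass
class RunConfig:
    """Validated experiment configuration (seed is always explicit)."""

    experiment: str
    seed: int
    params: dict = field(default_factory=dict)
    experiment_id: str = ""

    def __post_init__(self) -> None:
        errors = []
        if self.experiment not in _KNOWN_EXPERIMENTS:
            errors.append(
                f"experiment must be one of {_KNOWN_EXPERIMENTS}, got {self.experiment!r}"
            )
        if not isinstance(self.seed, (int, np.integer)):
            errors.append("seed must be an integer")
        if not isinstance(self.params, dict):
            errors.append("params must be a mapping")
        if errors:
            raise ValueError("invalid config: " + "; ".join(errors))
        if not self.experiment_id:
            self.experiment_id = f"{self.experiment}-{self.seed}"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            experiment=d.get("experiment", ""),
            seed=int(d.get("seed", 0)),
            params=dict(d.get("params", {})),
            experiment_id=d.get("experiment_id", ""),
        )

    def to_dict(self) -> dict:
        return {
            "experiment": self.experiment,
            "seed": self.seed,
            "params": copy.deepcopy(self.params),
            "experiment_id": self.experiment_id,
        }


#: Packaged configurations reproducing the study's synthetic counterparts:
#: the pre/post-HDL diffusion comparison and the spot-count partition map.
PACKAGED_CONFIGS: dict[str, dict] = {
    "fig2A_synthetic": {
        "experiment": "fcs_pre_post",
        "seed": 20,
        "params": {
            "d_pre": 9.6,  # um^2/s, tracer lipid before HDL incubation
            "d_post": 8.2,  # um^2/s, after incubation
            "n_vesicles": 5,
            "traces_per_vesicle": 3,
            "duration": 10.0,
            "dt": 50e-6,
            "w0": 0.25,
            "n_particles": 3.0,
        },
    },
    "fig1B_synthetic": {
        "experiment": "kp_spots",
        "seed": 11,
        "params": {
            "kp_true": 3.0,
            # low spot density: keeps diffraction-limited spots countable
            # (overlapping spots are dropped and would bias the ratio)
            "density2": 0.1,  # spots per um^2 in the ordered phase
            "shape": [512, 512],
        },
    },
}


def _run_fcs_pre_post(cfg: RunConfig) -> dict:
    p = cfg.params
    w0 = p.get("w0", fcs.W0_DEFAULT)
    summaries = {}
    for tag, d_true in (("pre", p.get("d_pre", 9.6)), ("post", p.get("d_post", 8.2))):
        fits, vesicles = [], []
        k = 0
        for v in range(p.get("n_vesicles", 5)):
            for _ in range(p.get("traces_per_vesicle", 3)):
                trace, _truth = synthetic.gen_fcs_trace(
                    d_true=d_true,
                    n_particles=p.get("n_particles", 3.0),
                    w0=w0,
                    duration=p.get("duration", 10.0),
                    dt=p.get("dt", 50e-6),
                    seed=cfg.seed * 10_000 + (0 if tag == "pre" else 5_000) + k,
                )
                k += 1
                curve = fcs.autocorrelate(trace)
                fits.append(fcs.fit_2d_triplet(curve, w0=w0, fit_triplet=False))
                vesicles.append(v)
        summaries[tag] = fcs.aggregate_sample(fits, vesicles)
    change = stats.relative_change(
        (summaries["pre"]["mean_d"], summaries["pre"]["se_d"]),
        (summaries["post"]["mean_d"], summaries["post"]["se_d"]),
    )
    return {
        "pre": summaries["pre"],
        "post": summaries["post"],
        "percent_decrease": change,
        "truth": {"d_pre": p.get("d_pre", 9.6), "d_post": p.get("d_post", 8.2)},
    }


def _run_kp_spots(cfg: RunConfig) -> dict:
    p = cfg.params
    kp_true = p.get("kp_true", 3.0)
    density2 = p.get("density2", 0.1)
    img = synthetic.gen_two_phase_image(
        density1=kp_true * density2,
        density2=density2,
        mode="point-emitters",
        shape=tuple(p.get("shape", (384, 384))),
        seed=cfg.seed,
    )
    mask = partition.make_phase_mask(img.channel_marker)
    locs = spt.detect_spots(img.channel_signal, pixel_size=img.pixel_size)
    result = partition.compute_kp_spots(locs, mask, pixel_size=img.pixel_size)
    return {
        "kp": result.kp,
        "se_kp": result.se_kp,
        "n_spots": int(result.i1 + result.i2),
        "truth": {"kp_true": kp_true},
    }


def _run_kp_intensity(cfg: RunConfig) -> dict:
    p = cfg.params
    kp_true = p.get("kp_true", 0.068)
    density2 = p.get("density2", 2e6)
    noise = synthetic.CameraNoise()
    img = synthetic.gen_two_phase_image(
        density1=kp_true * density2,
        density2=density2,
        mode="pixel-intensity",
        shape=tuple(p.get("shape", (256, 256))),
        noise=noise,
        seed=cfg.seed,
    )
    mask = partition.make_phase_mask(img.channel_marker)
    corrected = partition.background_correct(
        img.channel_signal, offset=noise.offset, clip=False
    )
    result = partition.compute_kp_intensity(
        partition.TwoChannelImage(img.channel_marker, corrected, img.pixel_size), mask
    )
    return {"kp": result.kp, "se_kp": result.se_kp, "truth": {"kp_true": kp_true}}


def _run_spt_mixture(cfg: RunConfig) -> dict:
    p = cfg.params
    trajs, truth = synthetic.gen_trajectory_mixture(
        n_traj=p.get("n_traj", 300),
        fractions=tuple(p.get("fractions", (0.7, 0.3, 0.0))),
        sigma_xy=p.get("sigma_xy", 30.0),
        radius=p.get("radius", 0.15),
        seed=cfg.seed,
    )
    sq = spt.square_displacements(trajs, n_values=[1, 2, 3])
    fit = spt.fit_bimodal_cdf(sq)
    fractions, _labels = spt.classify_mobility(trajs, sigma_xy=p.get("sigma_xy", 30.0))
    return {
        "alpha": fit.alpha,
        "fractions": fractions,
        "truth": dict(truth.parameters),
    }


def _run_gp_recovery(cfg: RunConfig) -> dict:
    p = cfg.params
    s440, s490, truth = synthetic.gen_gp_spectra(
        gp_true=p.get("gp_true", 0.3), noise_sd=p.get("noise_sd", 0.02), seed=cfg.seed
    )
    gp = laurdan.compute_gp_ex(s440, s490)
    mean, se = laurdan.summarize_gp(gp)
    return {"gp": mean, "se": se, "truth": dict(truth.parameters)}


_RUNNERS = {
    "fcs_pre_post": _run_fcs_pre_post,
    "kp_spots": _run_kp_spots,
    "kp_intensity": _run_kp_intensity,
    "spt_mixture": _run_spt_mixture,
    "gp_recovery": _run_gp_recovery,
}


def run_experiment(config: RunConfig | dict | str, out_dir=None) -> dict:
    """Execute one configured experiment end to end.

    ``config`` may be a :class:`RunConfig`, a plain dict, or the name of a
    packaged configuration.  Returns the result bundle (results + config +
    stage timings); with ``out_dir`` the bundle and the config are written
    as JSON.
    """
    if isinstance(config, str):
        if config not in PACKAGED_CONFIGS:
            raise ValueError(
                f"unknown packaged config {config!r}; available: {sorted(PACKAGED_CONFIGS)}"
            )
        config = RunConfig.from_dict(PACKAGED_CONFIGS[config])
    elif isinstance(config, dict):
        config = RunConfig.from_dict(config)

    t0 = time.perf_counter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = _RUNNERS[config.experiment](config)
    bundle = {
        "config": config.to_dict(),
        "results": results,
        "elapsed_s": round(time.perf_counter() - t0, 3),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / f"{config.experiment_id}.json").write_text(
            json.dumps(bundle, indent=2, default=_json_default)
        )
        log.info("wrote %s (%.1fs)", out / f"{config.experiment_id}.json", bundle["elapsed_s"])
    return bundle


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)
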