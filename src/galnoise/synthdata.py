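"""Synthetic single-cell fluorescence fixtures with known ground truth.

Stands in for raw flow-cytometry acquisitions: bimodal YFP distributions
over a panel of galactose doses, ~10,000 events per sample with scatter
channels, an autofluorescent OFF mode, and a log-normal ON mode whose
fraction follows a Hill dose response.  Each cell carries a latent size
factor that shifts both its (log) fluorescence and its scatter channels,
so extrinsic, size-linked variability can be removed by scatter gating —
the statistical structure the analysis pipeline assumes.

These mixtures are fast and analytically checkable; the mechanistic
counterpart of real measurements is the stochastic simulator.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np

from galnoise.cytometry import ExpressionSample, write_sample_csv

__all__ = [
    "GroundTruth",
    "generate_condition",
    "generate_panel",
    "default_panel_doses",
    "PRESETS",
]


def default_panel_doses() -> list[float]:
    """Eleven galactose doses spanning 0-0.5% w/v (0.08% background
    glucose is implicit in the dose-response parameters)."""
    return [0.0, 0.005, 0.01, 0.02, 0.03, 0.05, 0.075, 0.1, 0.15, 0.25, 0.5]


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters for one strain/topology analogue.

    The ON fraction follows ``f_max * s^h / (s^h + K^h)`` in galactose
    ``s``; ON-cell log-fluorescence is ``on_log_mean + ext_sd * z +
    int_sd * eps`` with ``z`` the cell's latent size factor (shared with
    the scatter channels — the extrinsic component) and ``eps`` private
    (intrinsic).  OFF cells draw from the autofluorescence log-normal,
    which also carries the size factor at reduced weight.
    """

    fraction_max: float = 0.95
    hill_K: float = 0.06        # % galactose at half-maximal ON fraction
    hill_n: float = 2.5
    on_log_mean: float = np.log(4000.0)
    intrinsic_log_sd: float = 0.15
    extrinsic_log_sd: float = 0.25
    autofluor_log_mean: float = np.log(300.0)
    autofluor_log_sd: float = 0.20
    scatter_log_mean: float = np.log(40.0)
    scatter_size_weight: float = 0.25
    scatter_noise_sd: float = 0.05
    cells_per_sample: int = 10_000
    seed: int = 0

    def fraction_on(self, galactose: float) -> float:
        if galactose <= 0:
            return 0.0
        sn = galactose ** self.hill_n
        return self.fraction_max * sn / (sn + self.hill_K ** self.hill_n)


#: two regimes for pipeline tests: a dosage-compensated-like network with a
#: small extrinsic component and a non-compensated-like one with a large one.
PRESETS: dict[str, GroundTruth] = {
    "compensated-like": GroundTruth(extrinsic_log_sd=0.12,
                                    intrinsic_log_sd=0.15),
    "noncompensated-like": GroundTruth(extrinsic_log_sd=0.30,
                                       intrinsic_log_sd=0.15),
}


def generate_condition(gt: GroundTruth, galactose: float,
                       n_cells: int | None = None,
                       seed: int | None = None) -> ExpressionSample:
    """Draw one sample at the given galactose dose.

    The RNG is seeded from ``(gt.seed, dose)`` so a panel is reproducible
    file-by-file; pass ``seed`` to override.
    """
    n = gt.cells_per_sample if n_cells is None else n_cells
    if n < 1:
        raise ValueError("n_cells must be >= 1")
    if seed is None:
        seed_key = [gt.seed, int(round(galactose * 1e6))]
    else:
        seed_key = [seed]
    rng = np.random.default_rng(seed_key)
    z = rng.standard_normal(n)           # latent size factor
    is_on = rng.random(n) < gt.fraction_on(galactose)
    eps = rng.standard_normal(n)
    log_fl = np.where(
        is_on,
        gt.on_log_mean + gt.extrinsic_log_sd * z + gt.intrinsic_log_sd * eps,
        gt.autofluor_log_mean + 0.5 * gt.extrinsic_log_sd * z
        + gt.autofluor_log_sd * eps,
    )
    fsc = np.exp(gt.scatter_log_mean + gt.scatter_size_weight * z
                 + gt.scatter_noise_sd * rng.standard_normal(n))
    ssc = 0.6 * np.exp(gt.scatter_log_mean + gt.scatter_size_weight * z
                       + gt.scatter_noise_sd * rng.standard_normal(n))
    meta = {"galactose": float(galactose), "label": "synthetic-fixture",
            "seed": gt.seed}
    return ExpressionSample(np.exp(log_fl), fsc, ssc, meta)


def generate_panel(gt: GroundTruth, out_dir: str | Path,
                   doses: list[float] | None = None) -> dict:
    """Write one CSV per dose plus a ground-truth manifest.

    The zero-dose file doubles as the uninduced sample for cutoff
    determination.  Returns the manifest (also written as JSON).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    doses = default_panel_doses() if doses is None else list(doses)
    if not any(d == 0 for d in doses):
        doses = [0.0] + doses
    manifest = {"ground_truth": {k: (v if not isinstance(v, np.floating)
                                     else float(v))
                                 for k, v in asdict(gt).items()},
                "samples": []}
    for d in sorted(doses):
        sample = generate_condition(gt, d)
        fname = f"sample_gal_{d:.6g}.csv"
        write_sample_csv(sample, out_dir / fname)
        manifest["samples"].append({
            "file": fname,
            "galactose": float(d),
            "fraction_on": gt.fraction_on(d),
            "n_cells": len(sample),
        })
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
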