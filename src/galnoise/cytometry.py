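"""Flow-cytometry-style analysis of single-cell expression samples.

Scatter gating to reduce cell-size contributions, an ON/OFF fluorescence
cutoff determined from uninduced samples, fraction-ON quantification, and
coefficient-of-variation (CV) noise quantification over ON cells only.
Applied identically to experimental-format CSV files and to simulated
endpoint samples (bridged by :func:`simulated_to_sample`).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from galnoise.cellsim import EndpointSample

__all__ = [
    "ExpressionSample",
    "GateConfig",
    "BimodalSummary",
    "gate",
    "determine_cutoff",
    "summarize",
    "simulated_to_sample",
    "read_sample_csv",
    "write_sample_csv",
    "EXCLUSION_GALACTOSE",
]

#: noise quantification excludes doses below this galactose concentration
#: (% w/v): too few ON cells for reliable CV estimates.
EXCLUSION_GALACTOSE = 0.075


@dataclass
class ExpressionSample:
    """Per-cell fluorescence and scatter for one induction condition."""

    fluorescence: np.ndarray
    forward_scatter: np.ndarray
    side_scatter: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fluorescence = np.asarray(self.fluorescence, float)
        self.forward_scatter = np.asarray(self.forward_scatter, float)
        self.side_scatter = np.asarray(self.side_scatter, float)
        n = len(self.fluorescence)
        if n < 1:
            raise ValueError("sample must contain at least one cell")
        if len(self.forward_scatter) != n or len(self.side_scatter) != n:
            raise ValueError("channel lengths differ")
        for ch in (self.fluorescence, self.forward_scatter, self.side_scatter):
            if not np.all(np.isfinite(ch)):
                raise ValueError("all channel values must be finite")

    def __len__(self) -> int:
        return len(self.fluorescence)

    @property
    def galactose(self) -> float | None:
        return self.metadata.get("galactose")


@dataclass(frozen=True)
class GateConfig:
    """Scatter gate.

    ``small_central`` keeps the ``target_fraction`` of cells closest to the
    scatter medians (smallest median-centred, MAD-scaled rectangle);
    ``middle_third`` keeps cells with both scatter values inside the
    central third of each axis's observed range; ``none`` is the identity.
    """

    gate_type: str = "small_central"
    target_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.gate_type not in ("small_central", "middle_third", "none"):
            raise ValueError(f"unknown gate type {self.gate_type!r}")
        if not 0.0 < self.target_fraction <= 1.0:
            raise ValueError("target_fraction must be in (0, 1]")


@dataclass(frozen=True)
class BimodalSummary:
    """Summary of one (possibly bimodal) expression distribution."""

    cutoff: float
    fraction_on: float
    n_on: int
    mean_on: float
    cv_on: float
    excluded_flag: bool
    cv_unreliable: bool = False
    n_total: int = 0
    metadata: dict = field(default_factory=dict)


def gate(sample: ExpressionSample, cfg: GateConfig) -> ExpressionSample:
    """Apply a forward/side-scatter gate; returns the retained subsample.

    Gating provenance is recorded in the subsample's metadata.
    """
    if cfg.gate_type == "none":
        out = replace(sample, metadata=dict(sample.metadata))
        out.metadata["gate"] = "none"
        return out
    fsc, ssc = sample.forward_scatter, sample.side_scatter
    if cfg.gate_type == "small_central":
        n = len(sample)
        k = max(1, round(cfg.target_fraction * n))
        mf, ms = np.median(fsc), np.median(ssc)
        sf = np.median(np.abs(fsc - mf)) or 1.0
        ss = np.median(np.abs(ssc - ms)) or 1.0
        d = np.maximum(np.abs(fsc - mf) / sf, np.abs(ssc - ms) / ss)
        keep = np.argsort(d, kind="stable")[:k]
        keep.sort()
    else:  # middle_third
        keep = np.ones(len(sample), bool)
        for ch in (fsc, ssc):
            lo, hi = ch.min(), ch.max()
            third = (hi - lo) / 3.0
            keep &= (ch >= lo + third) & (ch <= hi - third)
        keep = np.flatnonzero(keep)
    if len(keep) == 0:
        raise ValueError("gate retained no cells")
    meta = dict(sample.metadata)
    meta["gate"] = cfg.gate_type
    meta["gate_target_fraction"] = cfg.target_fraction
    meta["n_pregate"] = len(sample)
    return ExpressionSample(sample.fluorescence[keep], fsc[keep], ssc[keep],
                            meta)


def determine_cutoff(uninduced: ExpressionSample,
                     quantile: float = 0.995) -> float:
    """ON/OFF cutoff: a high quantile of the uninduced (zero-galactose)
    fluorescence distribution.

    The uninduced sample should already be gated the same way as the
    samples the cutoff will be applied to.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    if len(uninduced) < 100:
        raise ValueError("need >= 100 uninduced cells for a reliable quantile")
    g = uninduced.metadata.get("galactose")
    if g is not None and g > 0:
        raise ValueError("cutoff must come from a zero-galactose sample")
    return float(np.quantile(uninduced.fluorescence, quantile))


def summarize(sample: ExpressionSample, cutoff: float,
              min_on_cells: int = 50) -> BimodalSummary:
    """Fraction ON and ON-cell noise statistics at a fixed cutoff.

    ON cells are those with fluorescence strictly above the cutoff; the CV
    is the unbiased standard deviation over ON cells divided by their mean.
    Samples from galactose concentrations below ``EXCLUSION_GALACTOSE`` are
    flagged excluded; CV estimates from fewer than ``min_on_cells`` ON
    cells are flagged unreliable (reported, never dropped silently).
    """
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    fl = sample.fluorescence
    on = fl > cutoff
    n_on = int(on.sum())
    frac = n_on / len(fl)
    if n_on > 0:
        mean_on = float(fl[on].mean())
        sd_on = float(fl[on].std(ddof=1)) if n_on > 1 else 0.0
        cv_on = sd_on / mean_on if mean_on > 0 else np.nan
    else:
        mean_on = np.nan
        cv_on = np.nan
    g = sample.metadata.get("galactose")
    excluded = g is not None and g < EXCLUSION_GALACTOSE
    return BimodalSummary(
        cutoff=float(cutoff), fraction_on=frac, n_on=n_on, mean_on=mean_on,
        cv_on=cv_on, excluded_flag=bool(excluded),
        cv_unreliable=n_on < min_on_cells, n_total=len(fl),
        metadata=dict(sample.metadata),
    )


def simulated_to_sample(endpoint: EndpointSample,
                        c_fluor: float,
                        autofluor_log_mean: float,
                        autofluor_log_sd: float,
                        reporter: str = "YFP",
                        scatter_noise_sd: float = 0.1,
                        seed: int = 0) -> ExpressionSample:
    """Convert a simulated endpoint into a cytometry-style sample.

    Fluorescence is ``c_fluor * reporter_count`` plus a log-normal
    autofluorescence draw; forward/side scatter are synthesized from the
    simulated cell volume with multiplicative log-normal noise so that
    scatter gating selects on cell size, as in the instrument.
    """
    rng = np.random.default_rng(seed)
    counts = endpoint.species_counts(reporter)
    n = len(counts)
    autofl = rng.lognormal(autofluor_log_mean, autofluor_log_sd, n)
    fl = c_fluor * counts + autofl
    v = endpoint.volumes
    fsc = v * rng.lognormal(0.0, scatter_noise_sd, n)
    ssc = 0.6 * v * rng.lognormal(0.0, scatter_noise_sd, n)
    meta = dict(endpoint.metadata)
    meta["c_fluor"] = c_fluor
    return ExpressionSample(fl, fsc, ssc, meta)


_META_KEYS = ("galactose", "dox", "beta_estradiol", "topology", "ploidy",
              "copies", "seed", "replicate", "label")


def write_sample_csv(sample: ExpressionSample, path: str | Path) -> None:
    """Write a sample as CSV with a ``#``-prefixed provenance header."""
    path = Path(path)
    df = pd.DataFrame({
        "cell_id": np.arange(len(sample)),
        "fl_yfp": sample.fluorescence,
        "fsc": sample.forward_scatter,
        "ssc": sample.side_scatter,
    })
    buf = io.StringIO()
    for key in _META_KEYS:
        if key in sample.metadata:
            buf.write(f"# {key}: {sample.metadata[key]}\n")
    df.to_csv(buf, index=False, float_format="%.6g")
    path.write_text(buf.getvalue())


def read_sample_csv(path: str | Path) -> ExpressionSample:
    """Read a sample CSV written by :func:`write_sample_csv`."""
    path = Path(path)
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].partition(":")
            key, val = key.strip(), val.strip()
            try:
                num = float(val)
                meta[key] = int(num) if num == int(num) and "." not in val else num
            except ValueError:
                meta[key] = val
    df = pd.read_csv(path, comment="#")
    required = {"fl_yfp", "fsc", "ssc"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {required - set(df.columns)}")
    return ExpressionSample(df["fl_yfp"].to_numpy(), df["fsc"].to_numpy(),
                            df["ssc"].to_numpy(), meta)


def summaries_to_frame(summaries: list[BimodalSummary]) -> pd.DataFrame:
    """Tidy table of summaries, one row per condition."""
    rows = []
    for s in summaries:
        row = {k: s.metadata.get(k) for k in _META_KEYS if k in s.metadata}
        row.update(cutoff=s.cutoff, fraction_on=s.fraction_on, n_on=s.n_on,
                   mean_on=s.mean_on, cv_on=s.cv_on,
                   excluded_flag=s.excluded_flag,
                   cv_unreliable=s.cv_unreliable, n_total=s.n_total)
        rows.append(row)
    return pd.DataFrame(rows)
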