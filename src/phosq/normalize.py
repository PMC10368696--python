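"""Variance-stabilizing normalization of raw reporter intensities.

The error model is the standard additive–multiplicative one for reporter-ion
intensities: channel c measures  x = gain_c * mu * exp(eta) + offset_c + eps
with eta ~ N(0, sigma_m^2) and eps ~ N(0, sigma_a^2). Calibration is a
deliberately simple, fully deterministic fit of that model class:

* per-channel scale b_c: median ratio to the reference channel over complete
  rows (robust to a minority of differential rows);
* per-channel offset a_c: a low quantile (default 5%) of the residuals
  x_c − b_c * x_ref;
* one dataset-level glog scale lambda, estimated from the mean–variance
  relation of the calibrated data.

The variance-stabilizing transform is the generalized log

    h(x) = arsinh((x − a_c) / (2 * b_c * lambda)) / ln 2,

which behaves like log2 at high intensity (h(2x) − h(x) → 1), so differences
of h are log2-calibrated fold changes, while remaining bounded-variance at
low intensity. This is an approximation to full maximum-likelihood
variance-stabilizing calibration, chosen for reproducibility (no hidden
iteration); the model class is identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import QuantTable, ValidationError

_LN2 = float(np.log(2.0))


@dataclass
class AffineParams:
    """Per-channel affine calibration plus the dataset-level glog scale."""

    channels: list[str]
    offsets: np.ndarray  # a_c, additive
    scales: np.ndarray   # b_c > 0, multiplicative
    lam: float           # glog scale lambda > 0
    reference: str = ""

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.scales = np.asarray(self.scales, dtype=float)
        if np.any(self.scales <= 0):
            raise ValidationError("channel scales must be positive")
        if not self.lam > 0:
            raise ValidationError("glog scale lambda must be positive")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"channel_id": self.channels, "offset": self.offsets, "scale": self.scales}
        )
        df["lambda"] = self.lam
        df["reference"] = self.reference
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AffineParams":
        return cls(
            channels=[str(c) for c in df["channel_id"]],
            offsets=df["offset"].to_numpy(dtype=float),
            scales=df["scale"].to_numpy(dtype=float),
            lam=float(df["lambda"].iloc[0]),
            reference=str(df["reference"].iloc[0]),
        )


def _complete_rows(values: pd.DataFrame) -> np.ndarray:
    arr = values.to_numpy(dtype=float)
    return arr[np.isfinite(arr).all(axis=1)]


def fit_normalization(
    raw: QuantTable,
    *,
    reference: str | None = None,
    offset_quantile: float = 0.05,
    min_complete_rows: int = 10,
) -> AffineParams:
    """Fit per-channel affine calibration and the glog scale.

    The reference channel (default: first column) is fixed at a=0, b=1.
    """
    if raw.scale_tag != "raw":
        raise ValidationError("fit_normalization expects a raw-scale table")
    cols = list(raw.values.columns)
    if len(cols) < 2:
        raise ValidationError("normalization requires >= 2 channels")
    for c in cols:
        if not np.isfinite(raw.values[c].to_numpy(dtype=float)).any():
            raise ValidationError(f"channel {c!r} has no finite values")
    complete = _complete_rows(raw.values)
    if complete.shape[0] < min_complete_rows:
        raise ValidationError(
            f"normalization requires >= {min_complete_rows} complete rows, "
            f"got {complete.shape[0]}"
        )
    ref = reference or cols[0]
    ref_idx = cols.index(ref)
    xr = complete[:, ref_idx]
    pos = xr > 0
    if pos.sum() < min_complete_rows:
        raise ValidationError(f"reference channel {ref!r} has too few positive values")

    offsets = np.zeros(len(cols))
    scales = np.ones(len(cols))
    xr_pos = xr[pos]
    for j, c in enumerate(cols):
        if j == ref_idx:
            continue
        xc = complete[pos, j]
        # alternate the median-ratio scale with a low-quantile (background)
        # offset match; the pair converges geometrically to the affine fit.
        # Rows whose log-ratio deviates strongly (differential rows) are
        # trimmed by a MAD criterion before the quantile match, since
        # down-shifted outliers would otherwise pollute the low quantile.
        a, b = 0.0, 1.0
        inliers = np.ones(len(xc), dtype=bool)
        for _ in range(12):
            ratio = (xc - a) / xr_pos
            b = float(np.median(ratio))
            if not (np.isfinite(b) and b > 0):
                raise ValidationError(
                    f"could not estimate a positive scale for channel {c!r}"
                )
            valid = ratio > 0
            logr = np.where(valid, np.log(np.where(valid, ratio, 1.0) / b), np.inf)
            mad = float(np.median(np.abs(logr[valid] - np.median(logr[valid]))))
            if mad > 0:
                inliers = valid & (np.abs(logr - np.median(logr[valid])) <= 6.0 * mad)
            else:
                inliers = valid
            a = float(
                np.quantile(xc[inliers], offset_quantile)
                - b * np.quantile(xr_pos[inliers], offset_quantile)
            )
        scales[j] = b
        offsets[j] = a

    lam = _estimate_glog_scale(complete, offsets, scales)
    return AffineParams(channels=cols, offsets=offsets, scales=scales, lam=lam,
                        reference=ref)


def _estimate_glog_scale(complete: np.ndarray, offsets: np.ndarray,
                         scales: np.ndarray) -> float:
    """Estimate lambda from the mean–variance trend of calibrated rows.

    Under the additive–multiplicative model the per-row variance is
    sigma_a^2 + sigma_m^2 * mu^2, and arsinh(y / k) has approximately
    constant variance when k = sigma_a / sigma_m. The two components are
    separated by a robust (repeated-median) regression of row variance on
    squared row mean, so a minority of differential rows cannot distort
    them; lambda = k / 2.
    """
    y = (complete - offsets) / scales
    m = y.mean(axis=1)
    s2 = y.var(axis=1, ddof=1)
    ok = np.isfinite(m) & np.isfinite(s2)
    m, s2 = m[ok], s2[ok]
    if len(m) > 2000:  # repeated-median regression is quadratic in n
        order = np.argsort(m)
        m, s2 = m[order[:: len(m) // 2000 + 1]], s2[order[:: len(m) // 2000 + 1]]
    slope, intercept = sps.siegelslopes(s2, m**2)
    sigma_m = np.sqrt(max(float(slope), 1e-12))
    sigma_a = np.sqrt(max(float(intercept), 0.0))
    k = sigma_a / sigma_m
    scale_floor = 1e-6 * max(float(np.median(np.abs(m))), 1.0)
    return float(max(k / 2.0, scale_floor))


def glog_transform(raw: QuantTable, params: AffineParams) -> QuantTable:
    """Apply the calibrated generalized-log transform; missing stays missing."""
    if raw.scale_tag != "raw":
        raise ValidationError("glog_transform expects a raw-scale table")
    missing = [c for c in raw.values.columns if c not in params.channels]
    if missing:
        raise ValidationError(f"no calibration for channels {missing}")
    idx = [params.channels.index(c) for c in raw.values.columns]
    a = params.offsets[idx]
    b = params.scales[idx]
    arr = raw.values.to_numpy(dtype=float)
    h = np.arcsinh((arr - a) / (2.0 * b * params.lam)) / _LN2
    out = pd.DataFrame(h, index=raw.values.index, columns=raw.values.columns)
    return QuantTable(out, scale_tag="glog")
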