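"""Assemble per-lesion feature vectors into a cohort FeatureMatrix.

Default layout: 19 first-order features on the harmonized original
channel + 75 texture features on the sigma = 1 mm LoG channel = exactly
94 feature columns.  Wavelet-band first-order features can be computed
behind a flag but are always tagged ``excluded_by_default`` so selection
ignores them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..harmonization import HarmonizedChannels
from ..matrix import FIXED_CLINICAL, FeatureMatrix
from ..roi import ROI
from .firstorder import discretize, first_order_features
from .texture import texture_features

log = logging.getLogger(__name__)


@dataclass
class FeatureExtractionConfig:
    bin_width_orig: float = 25.0
    bin_width_log: float = 25.0
    texture_sigma_mm: float = 1.0
    include_wavelet: bool = False
    per_channel_texture: bool = False  # texture on every LoG channel


@dataclass
class LesionCase:
    lesion_id: str
    channels: HarmonizedChannels
    roi: ROI
    clinical: dict = field(default_factory=dict)


def extract_lesion_features(
    case: LesionCase, config: FeatureExtractionConfig | None = None
) -> dict[str, float]:
    """94 named features for one lesion (plus flagged extras if enabled)."""
    cfg = config or FeatureExtractionConfig()
    orig = case.channels.original
    vox_vol = float(np.prod(orig.spacing))
    vals = orig.values[case.roi.mask]
    out: dict[str, float] = {}
    for k, v in first_order_features(vals, vox_vol, cfg.bin_width_orig).items():
        out[f"orig_firstorder_{k}"] = v

    sigmas = (
        sorted(case.channels.log_channels)
        if cfg.per_channel_texture
        else [cfg.texture_sigma_mm]
    )
    for s in sigmas:
        if s not in case.channels.log_channels:
            raise KeyError(f"missing LoG channel sigma={s}")
        chan = case.channels.log_channels[s]
        levels3d = np.zeros(chan.values.shape, dtype=np.int64)
        levels3d[case.roi.mask] = discretize(
            chan.values[case.roi.mask], cfg.bin_width_log
        )
        tag = f"log-sigma-{s:g}mm"
        for k, v in texture_features(levels3d, case.roi.mask).items():
            out[f"{tag}_{k}"] = v

    if cfg.include_wavelet:
        out.update(_wavelet_features(orig.values, case.roi, cfg))
    return out


def _wavelet_features(values, roi: ROI, cfg) -> dict[str, float]:
    import pywt

    out = {}
    sub = roi.crop(values)
    coeffs = pywt.dwtn(sub, "haar")
    submask = roi.crop(roi.mask)
    for band, arr in sorted(coeffs.items()):
        # masks downsample by 2; a voxel survives if its 2x2x2 block did
        m = submask[::2, ::2, ::2]
        m = m[tuple(slice(0, s) for s in arr.shape)]
        a = arr[tuple(slice(0, s) for s in m.shape)]
        vals = a[m] if m.any() else a.ravel()
        for k, v in first_order_features(vals, 1.0, cfg.bin_width_orig).items():
            out[f"wavelet-{band}_firstorder_{k}"] = v
    return out


def extract_feature_matrix(
    cases: list[LesionCase], config: FeatureExtractionConfig | None = None
) -> FeatureMatrix:
    """Extract features for a cohort; failed lesions are dropped + counted."""
    cfg = config or FeatureExtractionConfig()
    rows, dropped = [], 0
    feature_names: list[str] | None = None
    for case in cases:
        try:
            feats = extract_lesion_features(case, cfg)
        except (KeyError, ValueError) as exc:
            log.warning("dropping lesion %s: %s", case.lesion_id, exc)
            dropped += 1
            continue
        if feature_names is None:
            feature_names = list(feats)
        row = {"lesion_id": case.lesion_id, **feats, **case.clinical}
        rows.append(row)
    if not rows:
        raise ValueError("no lesion could be extracted")
    data = pd.DataFrame(rows)

    excluded = [c for c in feature_names if c.startswith("wavelet")]
    selectable = [c for c in feature_names if not c.startswith("wavelet")]
    clinical_cols = [c for c in FIXED_CLINICAL if c in data.columns]
    meta = [
        c
        for c in data.columns
        if c not in selectable and c not in clinical_cols and c not in excluded
    ]
    # excluded wavelet columns live in the metadata block: present, never selected
    return FeatureMatrix(
        data=data,
        feature_columns=selectable,
        fixed_columns=clinical_cols,
        metadata_columns=meta + excluded,
        provenance={
            "families": {
                "firstorder": 19,
                "glcm": 24,
                "glrlm": 16,
                "glszm": 16,
                "gldm": 14,
                "ngtdm": 5,
            },
            "excluded_by_default": excluded,
            "dropped_lesions": dropped,
            "texture_channel": f"log-sigma-{cfg.texture_sigma_mm:g}mm",
        },
    )
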