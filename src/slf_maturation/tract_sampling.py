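"""Sampling metric maps along streamlines and reducing to tract means
(the tcksample-equivalent), plus assembly of the cohort table.

Values are sampled at streamline vertices by trilinear interpolation in
continuous voxel-index space (nearest-neighbour available via flag);
vertices whose interpolation stencil leaves the grid yield NaN and are
dropped — never zero-filled — from the mean.  The tract mean is
point-weighted by default: a plain average over all sampling points of
all streamlines, so longer streamlines weigh more; a streamline-weighted
mean (average of per-streamline means) is available as an option.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .errors import SamplingError
from .io_formats import Tractogram, VolumeImage

__all__ = [
    "sample_along_streamline",
    "tract_mean",
    "tract_mean_detail",
    "build_cohort_table",
]

log = logging.getLogger(__name__)

METRIC_BOUNDS = {
    "FA": (0.0, 1.0),
    "NDI": (0.0, 1.0),
    "ODI": (0.0, 1.0),
}


def sample_along_streamline(
    volume: VolumeImage,
    streamline: np.ndarray,
    interpolation: str = "trilinear",
) -> np.ndarray:
    """One value per vertex; NaN marks vertices outside the grid."""
    streamline = np.asarray(streamline, dtype=float)
    if streamline.ndim != 2 or streamline.shape[0] < 2:
        raise SamplingError("streamline must have >= 2 vertices")
    cont = volume.world_to_voxel(streamline)
    order = {"trilinear": 1, "nearest": 0}.get(interpolation)
    if order is None:
        raise SamplingError(f"unknown interpolation {interpolation!r}")
    return map_coordinates(
        np.asarray(volume.data, dtype=float),
        cont.T,
        order=order,
        mode="constant",
        cval=np.nan,
    )


def tract_mean_detail(
    volume: VolumeImage,
    bundle: Tractogram,
    weighting: str = "point",
    interpolation: str = "trilinear",
) -> tuple[float, int, int]:
    """Tract mean plus bookkeeping: (mean, n_points_used, n_dropped)."""
    if len(bundle) == 0:
        raise SamplingError("empty bundle: tract mean undefined")
    if weighting not in ("point", "streamline"):
        raise SamplingError(f"unknown weighting {weighting!r}")
    per_streamline = [
        sample_along_streamline(volume, s, interpolation=interpolation)
        for s in bundle.streamlines
    ]
    all_values = np.concatenate(per_streamline)
    valid = np.isfinite(all_values)
    n_dropped = int(np.sum(~valid))
    if not np.any(valid):
        raise SamplingError("all sampling points fall outside the grid")
    if weighting == "point":
        mean = float(np.mean(all_values[valid]))
    else:
        means = [
            float(np.nanmean(v)) for v in per_streamline if np.any(np.isfinite(v))
        ]
        mean = float(np.mean(means))
    return mean, int(np.sum(valid)), n_dropped


def tract_mean(
    volume: VolumeImage,
    bundle: Tractogram,
    weighting: str = "point",
    interpolation: str = "trilinear",
) -> float:
    """Mean metric value over all sampling points of all streamlines."""
    return tract_mean_detail(volume, bundle, weighting, interpolation)[0]


def build_cohort_table(
    subjects: Sequence[dict],
    bundles_per_subject: Sequence[dict],
    metrics_per_subject: Sequence[dict],
    bundle_names: Sequence[str] = ("SLF_I", "SLF_II", "SLF_III"),
    weighting: str = "point",
) -> pd.DataFrame:
    """Assemble the subject x (bundle x metric x hemisphere) table.

    ``subjects`` supplies one dict per subject (subject_id, group, age);
    ``bundles_per_subject`` maps ``{bundle}_{L|R}`` to that subject's
    dissected :class:`Tractogram`; ``metrics_per_subject`` maps metric name
    to :class:`VolumeImage`.  Emits per-hemisphere columns and the
    left/right-averaged column ``{bundle}_{metric}_LR`` (arithmetic mean of
    the two tract means).  Subjects with an empty bundle get NaN in that
    bundle's cells, and the omission is logged.
    """
    rows = []
    for subject, bundles, volumes in zip(
        subjects, bundles_per_subject, metrics_per_subject
    ):
        row = dict(subject)
        for bundle in bundle_names:
            for metric, volume in volumes.items():
                means = {}
                for hemi in ("L", "R"):
                    tract = bundles.get(f"{bundle}_{hemi}")
                    if tract is None or len(tract) == 0:
                        log.warning(
                            "subject %s: empty bundle %s_%s, cells set to NaN",
                            subject.get("subject_id"), bundle, hemi,
                        )
                        means[hemi] = np.nan
                    else:
                        means[hemi] = tract_mean(volume, tract, weighting=weighting)
                    row[f"{bundle}_{metric}_{hemi}"] = means[hemi]
                row[f"{bundle}_{metric}_LR"] = 0.5 * (means["L"] + means["R"])
        rows.append(row)
    return pd.DataFrame(rows)
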