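"""Virtual dissection: boolean include/exclude ROI selection of SLF
branches from a whole-brain tractogram.

A streamline is kept by a rule iff at least one tested point falls inside
every include ('AND') ROI — in any order along the streamline — and no
tested point touches any exclude ('NOT') ROI.  Tested points are the
vertices plus, by default, supersampled points so that consecutive tests
are at most half the smallest voxel edge apart; without supersampling a
long segment can jump clean across the one-voxel mid-sagittal slab and
silently defeat the callosal exclusion.

Point-to-voxel mapping uses the nearest-voxel convention: continuous
index c = affine^-1 . p, voxel i = floor(c + 0.5), i.e. voxel i spans
[i - 0.5, i + 0.5) in index space.  Points outside the grid are simply
outside every ROI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import yaml

from .errors import SelectionError
from .io_formats import Tractogram, VolumeImage

__all__ = [
    "SelectionRule",
    "Protocol",
    "load_protocol",
    "streamline_in_roi",
    "select_streamlines",
    "dissect_slf",
    "assign_ambiguous_by_height",
]


@dataclass(frozen=True)
class SelectionRule:
    name: str
    include: tuple
    exclude: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "include", tuple(self.include))
        object.__setattr__(self, "exclude", tuple(self.exclude))
        if not self.include:
            raise SelectionError(f"rule {self.name!r}: empty include set")
        if set(self.include) & set(self.exclude):
            raise SelectionError(
                f"rule {self.name!r}: include and exclude sets overlap"
            )


@dataclass(frozen=True)
class Protocol:
    name: str  # 'adult' or 'neonate'
    rules: tuple  # six SelectionRules (L/R x I/II/III)


def load_protocol(name: str, rules_path=None) -> Protocol:
    """Load a named dissection protocol from the packaged rule table (or a
    user YAML with the same layout)."""
    if rules_path is None:
        ref = resources.files("slf_maturation").joinpath("data/slf_rules.yaml")
        table = yaml.safe_load(ref.read_text())
    else:
        with open(rules_path) as fh:
            table = yaml.safe_load(fh)
    if name not in table:
        raise SelectionError(
            f"unknown protocol {name!r}; available: {sorted(table)}"
        )
    rules = tuple(
        SelectionRule(rule_name, spec["include"], spec["exclude"])
        for rule_name, spec in table[name].items()
    )
    return Protocol(name=name, rules=rules)


def _tested_points(streamline: np.ndarray, max_step: float | None) -> np.ndarray:
    """Vertices plus linearly interpolated points so that consecutive tested
    points are <= max_step apart (world mm)."""
    if max_step is None:
        return streamline
    seg = np.diff(streamline, axis=0)
    lengths = np.linalg.norm(seg, axis=1)
    n_sub = np.maximum(np.ceil(lengths / max_step).astype(int), 1)
    pieces = [streamline[:1]]
    for i in range(len(seg)):
        fractions = np.arange(1, n_sub[i] + 1) / n_sub[i]
        pieces.append(streamline[i] + fractions[:, None] * seg[i])
    return np.vstack(pieces)


def _labels_hit(
    streamline: np.ndarray, labels: VolumeImage, max_step: float | None
) -> set:
    """Set of label ids whose voxels the streamline's tested points touch."""
    pts = _tested_points(np.asarray(streamline, dtype=float), max_step)
    cont = labels.world_to_voxel(pts)
    idx = np.floor(cont + 0.5).astype(int)
    shape = np.array(labels.data.shape[:3])
    inside = np.all((idx >= 0) & (idx < shape), axis=1)
    if not np.any(inside):
        return set()
    idx = idx[inside]
    hit = labels.data[idx[:, 0], idx[:, 1], idx[:, 2]]
    return set(np.unique(hit[hit > 0]).tolist())


def _supersample_step(labels: VolumeImage) -> float:
    edges = np.linalg.norm(labels.affine[:3, :3], axis=0)
    return float(edges.min()) / 2.0


def streamline_in_roi(
    streamline: np.ndarray,
    labels: VolumeImage,
    label_id: int,
    supersample: bool = True,
) -> bool:
    """True iff any tested point of the streamline maps to a voxel carrying
    ``label_id``."""
    step = _supersample_step(labels) if supersample else None
    return label_id in _labels_hit(streamline, labels, step)


def _resolve_ids(names: Sequence[str], label_ids: dict) -> list:
    out = []
    for name in names:
        if name not in label_ids:
            raise SelectionError(f"unknown ROI label {name!r}")
        out.append(label_ids[name])
    return out


def _apply_rule(
    tractogram: Tractogram,
    rule: SelectionRule,
    label_ids: dict,
    hit_sets: list,
) -> tuple[Tractogram, list]:
    include = set(_resolve_ids(rule.include, label_ids))
    exclude = set(_resolve_ids(rule.exclude, label_ids))
    kept_idx = [
        i
        for i, hit in enumerate(hit_sets)
        if include <= hit and not (exclude & hit)
    ]
    kept = Tractogram(
        streamlines=[tractogram.streamlines[i] for i in kept_idx],
        header=dict(tractogram.header, rule=rule.name),
    )
    return kept, kept_idx


def select_streamlines(
    tractogram: Tractogram,
    rule: SelectionRule,
    labels: VolumeImage,
    label_ids: dict,
    supersample: bool = True,
) -> tuple[Tractogram, list]:
    """Apply one boolean rule; returns the kept sub-tractogram (input order
    preserved) and the kept indices."""
    step = _supersample_step(labels) if supersample else None
    hit_sets = [_labels_hit(s, labels, step) for s in tractogram.streamlines]
    return _apply_rule(tractogram, rule, label_ids, hit_sets)


def dissect_slf(
    tractogram: Tractogram,
    labels: VolumeImage,
    protocol: Protocol,
    label_ids: dict,
    supersample: bool = True,
) -> dict:
    """Apply all six rules of a protocol.

    Returns ``{rule name: (Tractogram, kept indices)}``.  A streamline
    satisfying two rules appears in both bundles (a warning is emitted);
    see :func:`assign_ambiguous_by_height` for the optional positional
    post-filter.
    """
    # hit sets are rule-independent: compute once, apply all six rules
    step = _supersample_step(labels) if supersample else None
    hit_sets = [_labels_hit(s, labels, step) for s in tractogram.streamlines]
    out = {}
    for rule in protocol.rules:
        out[rule.name] = _apply_rule(tractogram, rule, label_ids, hit_sets)
    seen: dict[int, str] = {}
    ambiguous = 0
    for name, (_, idx) in out.items():
        for i in idx:
            if i in seen:
                ambiguous += 1
            seen[i] = name
    if ambiguous:
        warnings.warn(
            f"{ambiguous} streamline(s) satisfy more than one bundle rule; "
            "reported in every matching bundle",
            stacklevel=2,
        )
    return out


def assign_ambiguous_by_height(
    tractogram: Tractogram,
    dissection: dict,
    dorsal_bundle: str,
    ventral_bundle: str,
) -> dict:
    """Resolve streamlines claimed by both a dorsal and a ventral bundle by
    mean z-coordinate: those above the mean height of the overlap go to the
    dorsal bundle, the rest to the ventral one.  Off by default in
    :func:`dissect_slf`; mirrors resolving SLF II/III overlap by dorsal
    versus ventral course."""
    _, dorsal_idx = dissection[dorsal_bundle]
    _, ventral_idx = dissection[ventral_bundle]
    overlap = sorted(set(dorsal_idx) & set(ventral_idx))
    if not overlap:
        return dissection
    heights = {i: float(np.mean(tractogram.streamlines[i][:, 2])) for i in overlap}
    cut = float(np.mean(list(heights.values())))
    new = dict(dissection)
    for name, keep_if_above in ((dorsal_bundle, True), (ventral_bundle, False)):
        _, idx = dissection[name]
        kept = [
            i
            for i in idx
            if i not in heights
            or (heights[i] >= cut if keep_if_above else heights[i] < cut)
        ]
        new[name] = (
            Tractogram(
                streamlines=[tractogram.streamlines[i] for i in kept],
                header=dict(tractogram.header, rule=name),
            ),
            kept,
        )
    return new
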