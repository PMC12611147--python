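"""Render simulation snapshots into two-channel frames and training pairs.

A frame is the surrogate's I/O unit: channel 0 is the binary vessel mask,
channel 1 the chemical field divided by a recorded normalization constant
(default: the saturation concentration ``secretion_rate / k``, the analytic
fixed point of the field equation, which puts typical concentrations at O(1)).
Training pairs match a frame at MCS ``t`` with the frame at ``t + horizon``
(default 100) from the same simulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from typing import List, Optional, Sequence, Tuple

import h5py
import numpy as np

from .cpm_core import LatticeState, ModelParams
from .vasculogenesis_model import SimulationRun

__all__ = [
    "TwoChannelFrame",
    "TrainingPair",
    "PairDataset",
    "default_normalization",
    "render_frame",
    "frames_from_run",
    "build_pairs",
    "split_dataset",
    "write_dataset",
    "read_dataset",
]

_FORMAT_VERSION = 1


@dataclass
class TwoChannelFrame:
    """(vessel mask, normalized field) image at a given MCS.

    Rendered frames have a strictly binary mask; frames produced by the
    surrogate carry mask *probabilities* in (0, 1) instead (binarization is
    the metrics module's concern).
    """

    mask: np.ndarray      # (H, W); {0,1} when rendered, probabilities when predicted
    field: np.ndarray     # (H, W) float32, concentration / normalization
    mcs: int
    sim_id: str = ""

    def __post_init__(self) -> None:
        if self.mask.shape != self.field.shape:
            raise ValueError("mask and field channels must share the lattice shape")

    @property
    def shape(self) -> tuple:
        return self.mask.shape

    def is_binary(self) -> bool:
        return bool(np.isin(np.unique(self.mask), (0, 1)).all())

    def to_array(self) -> np.ndarray:
        """Stack to (2, H, W) float32 — the network's native layout."""
        return np.stack(
            [self.mask.astype(np.float32), self.field.astype(np.float32)]
        )


@dataclass
class TrainingPair:
    input: TwoChannelFrame
    target: TwoChannelFrame
    horizon: int = 100

    def __post_init__(self) -> None:
        if self.input.sim_id != self.target.sim_id:
            raise ValueError("input and target must come from the same simulation")
        if self.target.mcs - self.input.mcs != self.horizon:
            raise ValueError("target.mcs - input.mcs must equal horizon")


def default_normalization(params: ModelParams) -> float:
    """Saturation concentration c* = secretion_rate / k (O(1) field scale)."""
    if params.k <= 0:
        raise ValueError("decay rate k must be > 0 to define the saturation scale")
    return params.secretion_rate / params.k


def render_frame(
    state: LatticeState, normalization: float, sim_id: str = ""
) -> TwoChannelFrame:
    """Binary cell-occupancy mask + field scaled by ``normalization``."""
    if normalization <= 0:
        raise ValueError("normalization must be > 0")
    return TwoChannelFrame(
        mask=(state.cell_id_lattice > 0).astype(np.uint8),
        field=(state.field / normalization).astype(np.float32),
        mcs=state.mcs,
        sim_id=sim_id,
    )


def frames_from_run(
    run: SimulationRun, normalization: Optional[float] = None, sim_id: Optional[str] = None
) -> List[TwoChannelFrame]:
    if normalization is None:
        normalization = default_normalization(run.params)
    if sim_id is None:
        sim_id = f"seed{run.seed}"
    return [
        TwoChannelFrame(
            mask=run.masks[i],
            field=(run.fields[i] / normalization).astype(np.float32),
            mcs=int(run.mcs_values[i]),
            sim_id=sim_id,
        )
        for i in range(len(run))
    ]


def build_pairs(
    snapshot_mcs_list: Sequence[int], horizon: int = 100
) -> List[Tuple[int, int]]:
    """Index pairs (i_input, i_target) with target exactly ``horizon`` MCS ahead.

    Convention: input times run over the half-open window
    ``[start, end - horizon)``, i.e. a pair is kept only when its target falls
    strictly before the final saved MCS.  On the full protocol window
    (200..20,000 at unit spacing) this yields 19,700 pairs per simulation.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    mcs = np.asarray(snapshot_mcs_list, dtype=np.int64)
    if len(mcs) == 0:
        return []
    index_of = {int(t): i for i, t in enumerate(mcs)}
    end = int(mcs.max())
    pairs = []
    for i, t in enumerate(mcs.tolist()):
        tgt = t + horizon
        if tgt < end and tgt in index_of:
            pairs.append((i, index_of[tgt]))
    return pairs


def split_dataset(
    pairs: Sequence,
    fraction: float = 0.8,
    seed: int = 0,
    groups: Optional[Sequence] = None,
) -> Tuple[list, list]:
    """Seeded shuffle split into (train, test); train gets floor(fraction*n).

    With ``groups`` (one label per pair, e.g. the simulation id) the shuffle
    happens at group level instead, so no simulation contributes to both
    sides — the leakage-free alternative to the default random-over-pairs
    split.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if len(pairs) == 0:
        raise ValueError("cannot split an empty pair list")
    rng = np.random.default_rng(seed)
    if groups is None:
        order = rng.permutation(len(pairs))
        n_train = int(np.floor(fraction * len(pairs)))
        train = [pairs[i] for i in order[:n_train]]
        test = [pairs[i] for i in order[n_train:]]
        return train, test
    if len(groups) != len(pairs):
        raise ValueError("groups must parallel pairs")
    labels = list(dict.fromkeys(groups))
    order = rng.permutation(len(labels))
    n_train_groups = int(np.floor(fraction * len(labels)))
    train_labels = {labels[i] for i in order[:n_train_groups]}
    train = [p for p, g in zip(pairs, groups) if g in train_labels]
    test = [p for p, g in zip(pairs, groups) if g not in train_labels]
    return train, test


@dataclass
class PairDataset:
    """Frames from one or more simulations plus a pair index table.

    ``pair_indices[j] = (i_in, i_tgt)`` index into the frame arrays; the
    normalization constant used for the field channel is recorded so raw
    concentrations can be recovered.
    """

    masks: np.ndarray            # (n_frames, H, W) uint8
    fields: np.ndarray           # (n_frames, H, W) float32 (normalized)
    mcs_values: np.ndarray       # (n_frames,) int64
    sim_ids: np.ndarray          # (n_frames,) int32: index into sim_labels
    sim_labels: list             # distinct simulation identifiers
    pair_indices: np.ndarray     # (n_pairs, 2) int64
    horizon: int
    normalization: float
    params_json: str = "{}"

    def __len__(self) -> int:
        return len(self.pair_indices)

    def frame(self, i: int) -> TwoChannelFrame:
        return TwoChannelFrame(
            mask=self.masks[i],
            field=self.fields[i],
            mcs=int(self.mcs_values[i]),
            sim_id=self.sim_labels[int(self.sim_ids[i])],
        )

    def pair(self, j: int) -> TrainingPair:
        i_in, i_tgt = self.pair_indices[j]
        return TrainingPair(self.frame(i_in), self.frame(i_tgt), self.horizon)

    @classmethod
    def from_runs(
        cls,
        runs: Sequence[SimulationRun],
        horizon: int = 100,
        normalization: Optional[float] = None,
    ) -> "PairDataset":
        """Concatenate runs; pairs never cross simulations."""
        if not runs:
            raise ValueError("need at least one run")
        if normalization is None:
            normalization = default_normalization(runs[0].params)
        masks, fields, mcs_all, sim_idx, pair_rows, labels = [], [], [], [], [], []
        offset = 0
        for r, run in enumerate(runs):
            labels.append(f"seed{run.seed}")
            masks.append(run.masks)
            fields.append((run.fields / normalization).astype(np.float32))
            mcs_all.append(run.mcs_values)
            sim_idx.append(np.full(len(run), r, dtype=np.int32))
            for i_in, i_tgt in build_pairs(run.mcs_values, horizon):
                pair_rows.append((i_in + offset, i_tgt + offset))
            offset += len(run)
        return cls(
            masks=np.concatenate(masks),
            fields=np.concatenate(fields),
            mcs_values=np.concatenate(mcs_all),
            sim_ids=np.concatenate(sim_idx),
            sim_labels=labels,
            pair_indices=np.asarray(pair_rows, dtype=np.int64).reshape(-1, 2),
            horizon=horizon,
            normalization=float(normalization),
            params_json=json.dumps(runs[0].params.to_dict()),
        )

    def subset(self, pair_rows: Sequence[Tuple[int, int]]) -> "PairDataset":
        """Same frames, restricted pair table (for train/test views)."""
        return PairDataset(
            masks=self.masks,
            fields=self.fields,
            mcs_values=self.mcs_values,
            sim_ids=self.sim_ids,
            sim_labels=self.sim_labels,
            pair_indices=np.asarray(list(pair_rows), dtype=np.int64).reshape(-1, 2),
            horizon=self.horizon,
            normalization=self.normalization,
            params_json=self.params_json,
        )


def write_dataset(dataset: PairDataset, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _FORMAT_VERSION
        f.attrs["horizon"] = dataset.horizon
        f.attrs["normalization"] = dataset.normalization
        f.attrs["params_json"] = dataset.params_json
        f.attrs["sim_labels"] = json.dumps(dataset.sim_labels)
        f.create_dataset("masks", data=dataset.masks, compression="gzip")
        f.create_dataset("fields", data=dataset.fields, compression="gzip")
        f.create_dataset("mcs_values", data=dataset.mcs_values)
        f.create_dataset("sim_ids", data=dataset.sim_ids)
        f.create_dataset("pair_indices", data=dataset.pair_indices)


def read_dataset(path: str) -> PairDataset:
    with h5py.File(path, "r") as f:
        if f.attrs.get("format_version") != _FORMAT_VERSION:
            raise ValueError(f"unsupported dataset format in {path}")
        masks = f["masks"][:]
        fields = f["fields"][:]
        if masks.shape != fields.shape:
            raise ValueError("corrupt dataset: mask/field shape mismatch")
        pair_indices = f["pair_indices"][:]
        if pair_indices.size and pair_indices.max() >= len(masks):
            raise ValueError("corrupt dataset: pair index out of range")
        return PairDataset(
            masks=masks,
            fields=fields,
            mcs_values=f["mcs_values"][:],
            sim_ids=f["sim_ids"][:],
            sim_labels=json.loads(f.attrs["sim_labels"]),
            pair_indices=pair_indices,
            horizon=int(f.attrs["horizon"]),
            normalization=float(f.attrs["normalization"]),
            params_json=f.attrs["params_json"],
        )
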