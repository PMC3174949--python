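"""Array geometry, peptide placement and control-class annotation.

A slide is a three-level hierarchy: an array holds ``n_subarrays`` identical
copies of the full peptide set (printed consecutively and stacked vertically,
so every peptide is replicated once per subarray), each subarray holds a
``grid_rows`` x ``grid_cols`` grid of blocks, and each block — deposited by a
single print tip ("needle") — holds ``rows_per_block`` x ``cols_per_block``
spots.  The GPR ``Block`` field numbers blocks row-major across the whole
slide, so corresponding blocks of different subarrays share a needle.

The default geometry is 3 subarrays x 16 blocks (4x4) x 20 rows x 20 columns
= 19200 spots, with 10% of spots carrying dedicated control peptides
(5% positive, 2.5% secondary-antibody, 1% negative, 1.5% process controls).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd

from rapmad.errors import BoundsError, DataError, PeptideLookupError

#: Recognised control classes, in scheduling order.
CONTROL_CLASSES = ("positive", "secondary_antibody", "negative", "process")

#: Fraction of all spots assigned to each control class by default.
DEFAULT_CONTROL_FRACTIONS = {
    "positive": 0.05,
    "secondary_antibody": 0.025,
    "negative": 0.01,
    "process": 0.015,
}

#: Distinct control peptide identities per class (13 in total, so the
#: control-only linear model sees a 12-df peptide factor).
DEFAULT_CONTROL_PEPTIDES = {
    "positive": 5,
    "secondary_antibody": 3,
    "negative": 2,
    "process": 3,
}

EXPERIMENTAL = "experimental"


@dataclass(frozen=True)
class ArrayLayout:
    """Hierarchical slide geometry."""

    n_subarrays: int = 3
    grid_rows: int = 4
    grid_cols: int = 4
    rows_per_block: int = 20
    cols_per_block: int = 20

    def __post_init__(self) -> None:
        for name in ("n_subarrays", "grid_rows", "grid_cols", "rows_per_block", "cols_per_block"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def blocks_per_subarray(self) -> int:
        return self.grid_rows * self.grid_cols

    @property
    def n_blocks(self) -> int:
        return self.n_subarrays * self.blocks_per_subarray

    @property
    def spots_per_block(self) -> int:
        return self.rows_per_block * self.cols_per_block

    @property
    def spots_per_subarray(self) -> int:
        return self.blocks_per_subarray * self.spots_per_block

    @property
    def n_spots(self) -> int:
        return self.n_subarrays * self.spots_per_subarray

    @property
    def n_global_rows(self) -> int:
        return self.n_subarrays * self.grid_rows * self.rows_per_block

    @property
    def n_global_cols(self) -> int:
        return self.grid_cols * self.cols_per_block


@dataclass(frozen=True)
class SpotAddress:
    """Physical position of one spot, resolved from GPR block coordinates."""

    subarray_id: int
    needle_id: int
    global_row: int
    global_col: int
    array_id: str = ""


class ControlAnnotation:
    """Mapping from peptide identifier to control class.

    Peptides absent from the mapping are experimental by default.
    """

    def __init__(self, mapping: Optional[dict[str, str]] = None):
        mapping = dict(mapping or {})
        for pid, cls in mapping.items():
            if cls not in CONTROL_CLASSES and cls != EXPERIMENTAL:
                raise ValueError(f"unknown control class {cls!r} for peptide {pid!r}")
        self._mapping = {p: c for p, c in mapping.items() if c != EXPERIMENTAL}

    def class_of(self, peptide_id: str) -> str:
        return self._mapping.get(peptide_id, EXPERIMENTAL)

    def peptides_of(self, cls: str) -> list[str]:
        if cls == EXPERIMENTAL:
            raise ValueError("experimental peptides are open-ended; enumerate from a design")
        return sorted(p for p, c in self._mapping.items() if c == cls)

    def items(self):
        return self._mapping.items()

    def __len__(self) -> int:
        return len(self._mapping)

    def __eq__(self, other) -> bool:
        return isinstance(other, ControlAnnotation) and self._mapping == other._mapping

    @classmethod
    def from_csv(cls, path) -> "ControlAnnotation":
        df = pd.read_csv(path)
        if not {"peptide_id", "class"}.issubset(df.columns):
            raise DataError(f"control annotation {path} needs columns peptide_id,class")
        return cls(dict(zip(df["peptide_id"].astype(str), df["class"].astype(str))))

    def to_csv(self, path) -> None:
        pd.DataFrame(sorted(self._mapping.items()), columns=["peptide_id", "class"]).to_csv(path, index=False)


def resolve_address(
    layout: ArrayLayout,
    block_id: int,
    row_in_block: int,
    col_in_block: int,
    array_id: str = "",
) -> SpotAddress:
    """Resolve GPR (Block, Row, Column) coordinates to the physical address.

    Blocks are numbered row-major across the whole slide; subarrays are the
    consecutive vertical bands of ``grid_rows`` block-rows, and the needle is
    the block's position within its subarray's grid (shared across subarrays).
    """
    if not (1 <= block_id <= layout.n_blocks):
        raise BoundsError(f"block_id {block_id} outside [1, {layout.n_blocks}]")
    if not (1 <= row_in_block <= layout.rows_per_block):
        raise BoundsError(f"row_in_block {row_in_block} outside [1, {layout.rows_per_block}]")
    if not (1 <= col_in_block <= layout.cols_per_block):
        raise BoundsError(f"col_in_block {col_in_block} outside [1, {layout.cols_per_block}]")
    block_row = (block_id - 1) // layout.grid_cols
    block_col = (block_id - 1) % layout.grid_cols
    subarray = block_row // layout.grid_rows + 1
    needle = (block_row % layout.grid_rows) * layout.grid_cols + block_col + 1
    global_row = block_row * layout.rows_per_block + row_in_block
    global_col = block_col * layout.cols_per_block + col_in_block
    return SpotAddress(subarray, needle, global_row, global_col, array_id)


def address_frame(layout: ArrayLayout, blocks, rows, cols) -> pd.DataFrame:
    """Vectorised :func:`resolve_address` over aligned coordinate arrays."""
    blocks = np.asarray(blocks, dtype=int)
    rows = np.asarray(rows, dtype=int)
    cols = np.asarray(cols, dtype=int)
    if (blocks < 1).any() or (blocks > layout.n_blocks).any():
        raise BoundsError("block index outside layout")
    if (rows < 1).any() or (rows > layout.rows_per_block).any():
        raise BoundsError("row index outside layout")
    if (cols < 1).any() or (cols > layout.cols_per_block).any():
        raise BoundsError("column index outside layout")
    block_row = (blocks - 1) // layout.grid_cols
    block_col = (blocks - 1) % layout.grid_cols
    return pd.DataFrame(
        {
            "subarray": block_row // layout.grid_rows + 1,
            "needle": (block_row % layout.grid_rows) * layout.grid_cols + block_col + 1,
            "global_row": block_row * layout.rows_per_block + rows,
            "global_col": block_col * layout.cols_per_block + cols,
        }
    )


def _control_slots(layout: ArrayLayout, n_ctrl: int, needle: int = 1) -> list[tuple[int, int]]:
    """Within-block (row, col) positions for ``n_ctrl`` control spots.

    Controls walk every block row cyclically while striding the columns, so
    each physical row and (for the default density) each physical column of
    every block carries controls — the linear model needs every global row
    and column level represented in the control set.  The pattern is rotated
    per needle: an identical pattern in every block puts accidental linear
    dependencies on the sparse control support and costs the fit estimable
    row/column levels.
    """
    R, C = layout.rows_per_block, layout.cols_per_block
    rng = np.random.default_rng(10_000 + needle)
    slots: list[tuple[int, int]] = []
    seen = set()
    k = 0
    while len(slots) < n_ctrl:
        perm = rng.permutation(C)
        for r0 in range(R):
            if len(slots) == n_ctrl:
                break
            r = r0 + 1
            c = int(perm[r0]) + 1
            if (r, c) in seen:  # fall back to the next free column in this row
                for cc in itertools.chain(range(c, C + 1), range(1, c)):
                    if (r, cc) not in seen:
                        c = cc
                        break
                else:
                    raise ValueError("block too small for requested control density")
            seen.add((r, c))
            slots.append((r, c))
        k += 1
        if k > C:
            raise ValueError("block too small for requested control density")
    return slots


def _class_schedule(n_slots: int, per_class: dict[str, int]) -> list[str]:
    """Interleave control classes evenly over ``n_slots`` block slots."""
    total = sum(per_class.values())
    assert total == n_slots
    assigned = {c: 0 for c in per_class}
    out = []
    for k in range(n_slots):
        # pick the class furthest behind its proportional quota
        cls = max(per_class, key=lambda c: per_class[c] * (k + 1) / n_slots - assigned[c])
        assigned[cls] += 1
        out.append(cls)
    return out


def build_design(
    layout: ArrayLayout = ArrayLayout(),
    control_fractions: Optional[dict[str, float]] = None,
    control_peptides: Optional[dict[str, int]] = None,
    seed: Optional[int] = None,
) -> tuple[pd.DataFrame, ControlAnnotation]:
    """Construct the peptide placement for one slide.

    Returns a per-spot DataFrame (one row per spot of the full array, all
    subarrays) with columns block, row, col, subarray, needle, global_row,
    global_col, peptide_id, control_class, and the matching annotation.
    Placement is deterministic unless ``seed`` is given, in which case the
    within-block control positions are permuted per block (for robustness
    tests); class scheduling and identities stay deterministic.
    """
    fractions = dict(control_fractions or DEFAULT_CONTROL_FRACTIONS)
    n_ids = dict(control_peptides or DEFAULT_CONTROL_PEPTIDES)
    unknown = set(fractions) - set(CONTROL_CLASSES)
    if unknown:
        raise ValueError(f"unknown control classes {sorted(unknown)}")
    spb = layout.spots_per_block
    per_class = {c: round(spb * fractions.get(c, 0.0)) for c in CONTROL_CLASSES}
    n_ctrl = sum(per_class.values())
    if n_ctrl >= spb:
        raise ValueError("control fraction leaves no experimental spots")
    for c, n in n_ids.items():
        if per_class.get(c, 0) > 0 and n < 1:
            raise ValueError(f"class {c} needs at least one peptide identity")

    ids = {c: [f"CTRL_{c.upper()[:3]}_{i + 1}" for i in range(n_ids.get(c, 1))] for c in CONTROL_CLASSES}
    schedule = _class_schedule(n_ctrl, per_class)
    rng = np.random.default_rng(seed) if seed is not None else None

    R, C = layout.rows_per_block, layout.cols_per_block
    n_exp_per_block = spb - n_ctrl
    class_counters = {c: 0 for c in CONTROL_CLASSES}

    # Build subarray 1; subarrays 2..n replicate it block-for-block.
    sub1_rows: list[tuple[int, int, int, str, str]] = []  # (needle, r, c, pid, cls)
    exp_counter = 0
    for needle in range(1, layout.blocks_per_subarray + 1):
        if rng is None:
            slots = _control_slots(layout, n_ctrl, needle)
        else:
            flat = rng.permutation(spb)[:n_ctrl]
            slots = [(int(p) // C + 1, int(p) % C + 1) for p in flat]
        slot_set = set(slots)
        # rotate the class sequence per needle as well, for the same reason
        rot = (needle - 1) % len(schedule)
        needle_schedule = schedule[rot:] + schedule[:rot]
        for (r, c), cls in zip(slots, needle_schedule):
            # offset by needle so a control identity is not glued to one
            # within-block position (that would alias peptide with position)
            idx = (class_counters[cls] + needle - 1) % len(ids[cls])
            class_counters[cls] += 1
            sub1_rows.append((needle, r, c, ids[cls][idx], cls))
        for r in range(1, R + 1):
            for c in range(1, C + 1):
                if (r, c) not in slot_set:
                    exp_counter += 1
                    sub1_rows.append((needle, r, c, f"PEP_{exp_counter:05d}", EXPERIMENTAL))
    assert exp_counter == layout.blocks_per_subarray * n_exp_per_block

    recs = []
    for s in range(1, layout.n_subarrays + 1):
        for needle, r, c, pid, cls in sub1_rows:
            block = (s - 1) * layout.blocks_per_subarray + needle
            recs.append((block, r, c, pid, cls))
    df = pd.DataFrame(recs, columns=["block", "row", "col", "peptide_id", "control_class"])
    df = pd.concat([df, address_frame(layout, df["block"], df["row"], df["col"])], axis=1)
    df = df.sort_values(["block", "row", "col"], kind="stable").reset_index(drop=True)

    annotation = ControlAnnotation(
        {pid: cls for cls in CONTROL_CLASSES for pid in ids[cls][: n_ids.get(cls, 1)] if per_class[cls] > 0}
    )
    return df, annotation


@lru_cache(maxsize=4)
def _cached_default_design() -> tuple[pd.DataFrame, ControlAnnotation]:
    return build_design(ArrayLayout())


def default_design() -> tuple[pd.DataFrame, ControlAnnotation]:
    """The default slide design (copy-safe)."""
    df, ann = _cached_default_design()
    return df.copy(), ann


def default_layout() -> tuple[ArrayLayout, ControlAnnotation]:
    """Default geometry and control annotation: 19200 spots, 10% controls."""
    _, ann = _cached_default_design()
    return ArrayLayout(), ann


ABSENT = None  # marker for a missing replicate


def replicates_of(
    peptide_id: str,
    values: pd.DataFrame,
    design: pd.DataFrame,
    layout: ArrayLayout = ArrayLayout(),
    value_column: str = "value",
) -> list:
    """Per-subarray replicate values of one peptide on one array.

    ``values`` holds one row per measured spot with columns block, row, col
    and ``value_column``; spots missing from it (e.g. flag-excluded) are
    reported as ``None`` in their subarray slot, never silently dropped.
    """
    placed = design.loc[design["peptide_id"] == peptide_id, ["block", "row", "col", "subarray"]]
    if placed.empty:
        raise PeptideLookupError(f"peptide {peptide_id!r} not on this design")
    merged = placed.merge(values[["block", "row", "col", value_column]], on=["block", "row", "col"], how="left")
    by_sub: dict[int, list] = {}
    for _, rec in merged.iterrows():
        v = rec[value_column]
        by_sub.setdefault(int(rec["subarray"]), []).append(None if pd.isna(v) else float(v))
    if all(all(v is None for v in vs) for vs in by_sub.values()):
        raise PeptideLookupError(f"peptide {peptide_id!r} absent from all subarrays")
    out = []
    for s in range(1, layout.n_subarrays + 1):
        vs = by_sub.get(s, [None])
        out.extend(vs)
    return out
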