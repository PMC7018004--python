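"""Rooted binary-tree morphologies ("florets") and their I/O.

A *floret* is the unit morphology modelled by this package: a rooted
strictly binary tree whose edges are *segments* — neurite stretches
between consecutive branch points, or between a branch point and a tip —
each carrying a length in micrometres.  Every internal segment has
exactly two children, so a floret with ``n`` segments has ``(n+1)/2``
terminal and ``(n-1)/2`` internal segments and ``n`` is odd.  A floret
with a single segment is called *trivial*.

Supported on-disk representations:

* SWC (the 7-column community standard for reconstructed neurites);
  chains of unary sample points are collapsed into single segments whose
  length is the summed 3D point-to-point distance.
* Flat segment tables (CSV, or XLSX when openpyxl is available) with
  floret id / segment id / parent id / length columns.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Iterator, Sequence
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .errors import (
    CycleError,
    DuplicateIdError,
    MalformedSWCError,
    MissingColumnError,
    MissingRootError,
    MorphologyError,
    MultipleRootsError,
    NonBinaryBranchingError,
    OrphanParentError,
    SegmentTooShortError,
    UnaryBranchPointError,
    UnknownSegmentError,
)

__all__ = [
    "Segment",
    "Floret",
    "Counts",
    "build_floret",
    "subfloret",
    "depths",
    "counts",
    "read_swc",
    "write_swc",
    "read_segment_table",
    "write_segment_table",
]

#: Measurement floor, in micrometres, enforced by :meth:`Floret.finalize`.
MIN_SEGMENT_LENGTH = 1.0


@dataclass(frozen=True)
class Segment:
    """One edge of the arbor; ``parent_id`` is ``None`` for the root."""

    id: int
    parent_id: Optional[int]
    length: float

    def __post_init__(self) -> None:
        if self.length < 0:
            raise MorphologyError(
                f"segment {self.id}: negative length {self.length!r}"
            )


class Counts(NamedTuple):
    n_segments: int
    n_terminals: int
    mean_length: float
    total_length: float


class Floret:
    """A validated rooted binary tree of :class:`Segment` objects.

    Parameters
    ----------
    segments:
        The segments of one tree, in any order.
    meta:
        Free-form provenance (seed, parameter set, source file, ...).
    coords:
        Optional 3D geometry: segment id -> ``(k, 3)`` polyline whose
        arc length equals the segment length.  Purely metadata; all
        statistics are computed from lengths and topology.
    """

    def __init__(
        self,
        segments: Iterable[Segment],
        meta: dict | None = None,
        coords: dict[int, np.ndarray] | None = None,
    ) -> None:
        self._segments: dict[int, Segment] = {}
        self._children: dict[int, list[int]] = {}
        root = None
        for seg in segments:
            if seg.id in self._segments:
                raise DuplicateIdError(f"duplicate segment id {seg.id}")
            self._segments[seg.id] = seg
            self._children.setdefault(seg.id, [])
            if seg.parent_id is None:
                if root is not None:
                    raise MultipleRootsError(
                        f"segments {root} and {seg.id} both claim to be root"
                    )
                root = seg.id
        if not self._segments:
            raise MissingRootError("a floret needs at least one segment")
        if root is None:
            raise MissingRootError("no segment without a parent")
        for seg in self._segments.values():
            if seg.parent_id is not None:
                if seg.parent_id not in self._segments:
                    raise OrphanParentError(
                        f"segment {seg.id} references unknown parent "
                        f"{seg.parent_id}"
                    )
                self._children[seg.parent_id].append(seg.id)
        self.root_id: int = root
        self.meta: dict = dict(meta or {})
        self.coords = coords
        self._preorder = self._validate()

    def _validate(self) -> list[int]:
        order: list[int] = []
        stack = [self.root_id]
        while stack:
            sid = stack.pop()
            order.append(sid)
            kids = self._children[sid]
            if len(kids) == 1:
                raise UnaryBranchPointError(
                    f"segment {sid} has exactly one child; bifurcations "
                    "must create two segments"
                )
            if len(kids) > 2:
                raise NonBinaryBranchingError(
                    f"segment {sid} has {len(kids)} children"
                )
            stack.extend(reversed(kids))
        if len(order) != len(self._segments):
            missing = set(self._segments) - set(order)
            raise CycleError(
                f"segments unreachable from root: {sorted(missing)[:5]}..."
            )
        return order

    # -- basic queries -------------------------------------------------

    def __len__(self) -> int:
        return len(self._segments)

    def __contains__(self, sid: int) -> bool:
        return sid in self._segments

    def __iter__(self) -> Iterator[Segment]:
        return (self._segments[sid] for sid in self._preorder)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Floret n={len(self)} root={self.root_id}>"

    def segment(self, sid: int) -> Segment:
        try:
            return self._segments[sid]
        except KeyError:
            raise UnknownSegmentError(sid) from None

    def children(self, sid: int) -> tuple[int, ...]:
        if sid not in self._segments:
            raise UnknownSegmentError(sid)
        return tuple(self._children[sid])

    def preorder(self) -> list[int]:
        """Segment ids, root first, children in insertion order."""
        return list(self._preorder)

    @property
    def n_segments(self) -> int:
        return len(self._segments)

    @property
    def n_terminals(self) -> int:
        return (len(self._segments) + 1) // 2

    @property
    def n_internal(self) -> int:
        return (len(self._segments) - 1) // 2

    @property
    def is_trivial(self) -> bool:
        return len(self._segments) == 1

    @property
    def lengths(self) -> np.ndarray:
        """Segment lengths in preorder, micrometres."""
        return np.array(
            [self._segments[sid].length for sid in self._preorder]
        )

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())

    def terminal_ids(self) -> list[int]:
        return [sid for sid in self._preorder if not self._children[sid]]

    def depths(self) -> dict[int, int]:
        """Depth per segment: root has depth 1, +1 at each bifurcation."""
        out = {self.root_id: 1}
        for sid in self._preorder[1:]:
            out[sid] = out[self._segments[sid].parent_id] + 1
        return out

    def counts(self) -> Counts:
        lens = self.lengths
        return Counts(
            n_segments=len(lens),
            n_terminals=self.n_terminals,
            mean_length=float(lens.mean()),
            total_length=float(lens.sum()),
        )

    def subfloret(self, sid: int) -> "Floret":
        """The sub-tree rooted at ``sid`` (``sid`` plus all descendants)."""
        if sid not in self._segments:
            raise UnknownSegmentError(sid)
        keep: list[Segment] = []
        stack = [sid]
        while stack:
            cur = stack.pop()
            seg = self._segments[cur]
            if cur == sid:
                seg = Segment(seg.id, None, seg.length)
            keep.append(seg)
            stack.extend(self._children[cur])
        coords = None
        if self.coords is not None:
            coords = {s.id: self.coords[s.id] for s in keep if s.id in self.coords}
        return Floret(keep, meta={"subfloret_of": self.meta.get("name"), "root": sid}, coords=coords)

    def finalize(self, min_length: float = MIN_SEGMENT_LENGTH) -> "Floret":
        """Validate the measurement floor (segments >= 1 micron).

        Zero- or short-length segments are legal mid-simulation but not
        in a finalized floret; this check mirrors the measurement
        precision cut applied to reconstructed data.
        """
        short = [s.id for s in self if s.length < min_length]
        if short:
            raise SegmentTooShortError(
                f"segments below {min_length} um: {short[:5]}"
            )
        return self


def build_floret(
    rows: Sequence[tuple[int, Optional[int], float]],
    meta: dict | None = None,
) -> Floret:
    """Build and validate a floret from ``(id, parent_id, length)`` rows."""
    return Floret([Segment(int(i), None if p is None else int(p), float(l))
                   for i, p, l in rows], meta=meta)


def subfloret(f: Floret, sid: int) -> Floret:
    return f.subfloret(sid)


def depths(f: Floret) -> dict[int, int]:
    return f.depths()


def counts(f: Floret) -> Counts:
    return f.counts()


# ---------------------------------------------------------------------------
# SWC
# ---------------------------------------------------------------------------

_ABSTRACT_HEADER = (
    "# abstract geometry: florets written as polylines along +z; "
    "coordinates are bookkeeping only, segment lengths are exact"
)


def read_swc(path: str | Path) -> list[Floret]:
    """Read an SWC file into a list of florets (one per SWC tree).

    Chains of unary sample points are collapsed into single segments;
    the segment length is the summed 3D point-to-point distance,
    including the step from the parent branch point to the segment's
    first own sample.  A sample with more than two children raises
    :class:`NonBinaryBranchingError`.
    """
    path = Path(path)
    xyz: dict[int, np.ndarray] = {}
    parent: dict[int, int] = {}
    children: dict[int, list[int]] = {}
    roots: list[int] = []
    order: list[int] = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise MalformedSWCError(f"{path}:{ln}: expected 7 columns")
        try:
            idx = int(parts[0])
            x, y, z = (float(v) for v in parts[2:5])
            par = int(parts[6])
        except ValueError as exc:
            raise MalformedSWCError(f"{path}:{ln}: {exc}") from None
        if idx in xyz:
            raise MalformedSWCError(f"{path}:{ln}: duplicate sample {idx}")
        xyz[idx] = np.array([x, y, z])
        children.setdefault(idx, [])
        order.append(idx)
        if par == -1:
            roots.append(idx)
        else:
            if par not in xyz:
                raise MalformedSWCError(
                    f"{path}:{ln}: sample {idx} before its parent {par}"
                )
            parent[idx] = par
            children[par].append(idx)
    if not roots:
        raise MalformedSWCError(f"{path}: no root sample")

    florets = []
    for root in roots:
        florets.append(_extract_floret(root, xyz, children, str(path)))
    return florets


def _extract_floret(
    root: int,
    xyz: dict[int, np.ndarray],
    children: dict[int, list[int]],
    source: str,
) -> Floret:
    segments: list[Segment] = []
    coords: dict[int, np.ndarray] = {}
    next_id = 1
    # work items: (segment parent id or None, anchor sample, first own sample)
    stack: list[tuple[Optional[int], Optional[int], int]] = [(None, None, root)]
    while stack:
        par_seg, anchor, start = stack.pop()
        sid = next_id
        next_id += 1
        pts = [] if anchor is None else [xyz[anchor]]
        length = 0.0
        cur = start
        while True:
            pts.append(xyz[cur])
            if len(pts) > 1:
                length += float(np.linalg.norm(pts[-1] - pts[-2]))
            kids = children[cur]
            if len(kids) == 1:
                cur = kids[0]
                continue
            if len(kids) > 2:
                raise NonBinaryBranchingError(
                    f"{source}: sample {cur} has {len(kids)} children"
                )
            break
        segments.append(Segment(sid, par_seg, length))
        coords[sid] = np.array(pts)
        for kid in reversed(children[cur]):
            stack.append((sid, cur, kid))
    return Floret(segments, meta={"source": source}, coords=coords)


def write_swc(florets: Iterable[Floret], path: str | Path) -> None:
    """Write florets to a single SWC file, one SWC tree per floret.

    Florets carrying 3D polylines (``coords``) are written with their
    real geometry; florets without coordinates are written as abstract
    polylines along +z (declared in a header comment).  Segment lengths
    round-trip to 1e-6 um.
    """
    path = Path(path)
    lines: list[str] = ["# SWC written by floretgen"]
    if any(f.coords is None for f in florets):
        lines.append(_ABSTRACT_HEADER)
    offset = 0
    for floret in florets:
        offset = _append_swc_tree(floret, lines, offset)
    path.write_text("\n".join(lines) + "\n")


def _append_swc_tree(floret: Floret, lines: list[str], offset: int) -> int:
    idx = offset
    last_sample: dict[int, int] = {}  # segment id -> distal SWC sample index
    tip_pos: dict[int, np.ndarray] = {}

    def emit(pos: np.ndarray, par: int) -> int:
        nonlocal idx
        idx += 1
        lines.append(
            f"{idx} 2 {pos[0]:.6f} {pos[1]:.6f} {pos[2]:.6f} 0.5 {par}"
        )
        return idx

    for sid in floret.preorder():
        seg = floret.segment(sid)
        if floret.coords is not None and sid in floret.coords:
            pts = floret.coords[sid]
            if seg.parent_id is None:
                par = -1
            else:
                par = last_sample[seg.parent_id]
                pts = pts[1:]  # first point is the parent anchor
            for p in pts:
                par = emit(np.asarray(p, dtype=float), par)
            last_sample[sid] = par
        else:
            if seg.parent_id is None:
                start = np.zeros(3)
                par = emit(start, -1)
            else:
                start = tip_pos[seg.parent_id]
                par = last_sample[seg.parent_id]
            tip = start + np.array([0.0, 0.0, seg.length])
            par = emit(tip, par)
            last_sample[sid] = par
            tip_pos[sid] = tip
    return idx


# ---------------------------------------------------------------------------
# Flat segment tables
# ---------------------------------------------------------------------------

DEFAULT_COLUMNS = {
    "floret": "floret_id",
    "segment": "segment_id",
    "parent": "parent_id",
    "length": "length",
}


def _read_table(path: Path) -> pd.DataFrame:
    if path.suffix.lower() in {".xlsx", ".xls"}:
        return pd.read_excel(path)
    return pd.read_csv(path)


def read_segment_table(
    path: str | Path,
    columns: dict[str, str] | None = None,
) -> list[Floret]:
    """Read a flat segment table (CSV/XLSX) into florets.

    The table needs segment id, parent id and length columns; a floret
    id column groups rows into florets (absent: the file is one floret).
    Parent values that are missing, negative or the strings ``none`` /
    ``root`` mark the root segment.  Column names can be remapped via
    ``columns`` (keys: floret, segment, parent, length).
    """
    path = Path(path)
    cols = dict(DEFAULT_COLUMNS)
    cols.update(columns or {})
    df = _read_table(path)
    for key in ("segment", "parent", "length"):
        if cols[key] not in df.columns:
            raise MissingColumnError(
                f"{path}: missing column {cols[key]!r}"
            )

    def parse_parent(value) -> Optional[int]:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return None
        if isinstance(value, str) and value.strip().lower() in {"", "none", "root", "na"}:
            return None
        iv = int(float(value))
        return None if iv < 0 else iv

    florets = []
    if cols["floret"] in df.columns:
        groups = df.groupby(cols["floret"], sort=True)
    else:
        groups = [(path.stem, df)]
    for fid, grp in groups:
        rows = [
            (int(r[cols["segment"]]), parse_parent(r[cols["parent"]]),
             float(r[cols["length"]]))
            for _, r in grp.iterrows()
        ]
        florets.append(build_floret(rows, meta={"source": str(path), "floret_id": fid}))
    return florets


def write_segment_table(florets: Iterable[Floret], path: str | Path) -> None:
    """Write florets as a flat CSV segment table (read back by
    :func:`read_segment_table`)."""
    records = []
    for i, floret in enumerate(florets, start=1):
        fid = floret.meta.get("floret_id", i)
        for seg in floret:
            records.append(
                {
                    "floret_id": fid,
                    "segment_id": seg.id,
                    "parent_id": -1 if seg.parent_id is None else seg.parent_id,
                    "length": seg.length,
                }
            )
    pd.DataFrame.from_records(records).to_csv(path, index=False)
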