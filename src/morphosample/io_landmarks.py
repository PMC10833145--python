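"""Reading and writing 2D landmark data.

Supports the tpsDIG dialect of the TPS landmark file format (``LM=`` records
with optional ``CURVES=``/``POINTS=`` blocks and ``IMAGE=``/``ID=``/``SCALE=``
trailer lines), slider-definition tables (before/slide/after triplets) and
specimen classifier tables.  Landmark indices are 0-based everywhere in
memory and 1-based in files, matching the convention of the tps software
series.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("morphosample")

__all__ = [
    "SpecimenConfig",
    "SliderTable",
    "LandmarkDataset",
    "TPSParseError",
    "read_tps",
    "write_tps",
    "make_sliders_from_curves",
    "read_sliders_csv",
    "write_sliders_csv",
    "read_classifiers_csv",
]

REQUIRED_CLASSIFIER_COLUMNS = ("id", "species", "sex", "view")


class TPSParseError(ValueError):
    """Raised when a TPS file violates the expected dialect."""


@dataclass
class SpecimenConfig:
    """A single specimen: a k x 2 landmark configuration.

    Coordinates are stored in file order (fixed landmarks first, curve
    points appended in curve order), x then y, in arbitrary units. ``scale``
    is the tpsDIG pixel-to-unit factor; when present it has already been
    applied multiplicatively to ``coords``.
    """

    id: str
    coords: np.ndarray
    scale: float | None = None
    image_ref: str | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(f"specimen {self.id!r}: coords must be k x 2")
        if self.coords.shape[0] < 3:
            raise ValueError(f"specimen {self.id!r}: need at least 3 landmarks")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"specimen {self.id!r}: non-finite coordinates")
        self._warn_coincident()

    def _warn_coincident(self, tol: float = 1e-12) -> None:
        c = self.coords - self.coords.mean(axis=0)
        size = float(np.sqrt((c**2).sum()))
        if size == 0.0:
            warnings.warn(f"specimen {self.id!r}: degenerate (all landmarks coincident)")
            return
        c = c / size
        d2 = ((c[:, None, :] - c[None, :, :]) ** 2).sum(-1)
        iu = np.triu_indices_from(d2, k=1)
        if np.any(d2[iu] < tol**2):
            warnings.warn(f"specimen {self.id!r}: coincident landmarks after unit scaling")

    @property
    def k(self) -> int:
        return self.coords.shape[0]


@dataclass
class SliderTable:
    """Semilandmark slider definitions: rows of (before, slide, after).

    Indices are 0-based landmark indices.  Each sliding point appears in at
    most one row and slides along the chord from its ``before`` to its
    ``after`` neighbour.
    """

    rows: np.ndarray  # (s, 3) int

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=int).reshape(-1, 3)

    def validate(self, k: int) -> None:
        r = self.rows
        if r.size == 0:
            return
        if r.min() < 0 or r.max() >= k:
            raise ValueError(f"slider index out of range for k={k}")
        for i, (b, s, a) in enumerate(r):
            if len({b, s, a}) != 3:
                raise ValueError(f"slider row {i}: indices not distinct: {(b, s, a)}")
        slides = r[:, 1]
        if len(set(slides.tolist())) != len(slides):
            raise ValueError("a landmark appears as 'slide' in more than one row")

    @property
    def n_sliders(self) -> int:
        return self.rows.shape[0]

    @property
    def sliding_indices(self) -> np.ndarray:
        return self.rows[:, 1]

    def __len__(self) -> int:
        return self.n_sliders


@dataclass
class LandmarkDataset:
    """An ordered collection of specimens sharing one landmark scheme."""

    specimens: list[SpecimenConfig]
    sliders: SliderTable = field(default_factory=lambda: SliderTable(np.empty((0, 3), int)))
    classifiers: pd.DataFrame | None = None
    dim: int = 2

    def __post_init__(self) -> None:
        if len(self.specimens) < 1:
            raise ValueError("dataset needs at least one specimen")
        ks = {s.k for s in self.specimens}
        if len(ks) != 1:
            raise ValueError(f"specimens disagree on landmark count: {sorted(ks)}")
        self.sliders.validate(self.k)
        if self.classifiers is not None:
            self._check_classifier_join()

    def _check_classifier_join(self) -> None:
        cls = self.classifiers
        missing = [c for c in REQUIRED_CLASSIFIER_COLUMNS if c not in cls.columns]
        if missing:
            raise ValueError(f"classifier table missing columns: {missing}")
        ids = cls["id"].astype(str)
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].tolist()
            raise ValueError(f"duplicate classifier ids: {dup}")
        have = set(ids)
        absent = [s.id for s in self.specimens if s.id not in have]
        if absent:
            raise ValueError(f"specimens without classifier rows: {absent}")

    @property
    def n(self) -> int:
        return len(self.specimens)

    @property
    def k(self) -> int:
        return self.specimens[0].k

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.specimens]

    def coords_array(self) -> np.ndarray:
        """Stack all configurations into an (n, k, 2) array."""
        return np.stack([s.coords for s in self.specimens])

    def classifier_column(self, name: str) -> np.ndarray:
        """Classifier column values in specimen order."""
        if self.classifiers is None:
            raise ValueError("dataset has no classifier table")
        lut = self.classifiers.set_index(self.classifiers["id"].astype(str))[name]
        return np.asarray([lut[s.id] for s in self.specimens])

    def subset(self, indices: Sequence[int]) -> "LandmarkDataset":
        """A new dataset restricted to the given specimen positions."""
        specs = [self.specimens[i] for i in indices]
        cls = None
        if self.classifiers is not None:
            keep = {s.id for s in specs}
            cls = self.classifiers[self.classifiers["id"].astype(str).isin(keep)].reset_index(drop=True)
        return LandmarkDataset(specs, sliders=self.sliders, classifiers=cls)

    def with_classifiers(self, classifiers: pd.DataFrame) -> "LandmarkDataset":
        return LandmarkDataset(list(self.specimens), sliders=self.sliders, classifiers=classifiers)


# ---------------------------------------------------------------------------
# TPS files
# ---------------------------------------------------------------------------

def _parse_key(line: str) -> tuple[str, str] | None:
    if "=" not in line:
        return None
    key, val = line.split("=", 1)
    return key.strip().upper(), val.strip()


def read_tps(path: str | Path, curve_anchors: Sequence[tuple[int, int]] | None = None) -> LandmarkDataset:
    """Read a TPS file into a :class:`LandmarkDataset` (without classifiers).

    Curve points are appended after the fixed landmarks in curve order and a
    slider table is generated from the curve structure.  By default each
    curve's first and last points act as the fixed anchors of that curve
    (interior points slide); pass ``curve_anchors`` as one ``(before, after)``
    landmark-index pair per curve to make every curve point slide against
    named fixed landmarks instead.

    SCALE factors, when present, are applied multiplicatively to the
    coordinates and logged.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    if not any(ln.strip() for ln in lines):
        raise TPSParseError(f"{path}: empty file")

    specimens: list[SpecimenConfig] = []
    curve_layouts: list[tuple[int, list[int]]] = []  # (n_fixed, curve point counts)
    i = 0
    nline = len(lines)

    def read_points(n: int, what: str) -> np.ndarray:
        nonlocal i
        pts = np.empty((n, 2))
        for j in range(n):
            while i < nline and not lines[i].strip():
                i += 1
            if i >= nline:
                raise TPSParseError(f"{path}: unexpected end of file inside {what}")
            parts = lines[i].split()
            if len(parts) < 2:
                raise TPSParseError(f"{path}:{i + 1}: expected coordinate pair in {what}")
            try:
                pts[j] = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise TPSParseError(f"{path}:{i + 1}: non-numeric coordinate {parts[:2]}") from exc
            i += 1
        return pts

    while i < nline:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        kv = _parse_key(line)
        if kv is None or kv[0] != "LM":
            raise TPSParseError(f"{path}:{i + 1}: expected LM= record start, got {line!r}")
        rec_line = i + 1
        try:
            n_fixed = int(kv[1])
        except ValueError as exc:
            raise TPSParseError(f"{path}:{i + 1}: bad LM count {kv[1]!r}") from exc
        i += 1
        fixed = read_points(n_fixed, f"record at line {rec_line}")

        curves: list[np.ndarray] = []
        scale: float | None = None
        image_ref: str | None = None
        spec_id: str | None = None
        while i < nline:
            nxt = lines[i].strip()
            if not nxt:
                i += 1
                continue
            kv = _parse_key(nxt)
            if kv is None:
                raise TPSParseError(f"{path}:{i + 1}: unexpected line {nxt!r}")
            key, val = kv
            if key == "LM":
                break
            if key == "CURVES":
                n_curves = int(val)
                i += 1
                for c in range(n_curves):
                    while i < nline and not lines[i].strip():
                        i += 1
                    pkv = _parse_key(lines[i].strip()) if i < nline else None
                    if pkv is None or pkv[0] != "POINTS":
                        raise TPSParseError(
                            f"{path}:{i + 1}: expected POINTS= for curve {c + 1} of record at line {rec_line}"
                        )
                    npts = int(pkv[1])
                    i += 1
                    curves.append(read_points(npts, f"curve {c + 1} of record at line {rec_line}"))
            elif key == "POINTS":
                raise TPSParseError(f"{path}:{i + 1}: POINTS= outside a CURVES block (record at line {rec_line})")
            elif key == "IMAGE":
                image_ref = val
                i += 1
            elif key == "ID":
                spec_id = val
                i += 1
            elif key == "SCALE":
                scale = float(val)
                i += 1
            else:
                logger.warning("%s:%d: ignoring unknown key %r", path, i + 1, key)
                i += 1

        coords = np.vstack([fixed] + curves) if curves else fixed
        if scale is not None:
            coords = coords * scale
            logger.info("applied SCALE=%g to record at line %d", scale, rec_line)
        if spec_id is None:
            spec_id = f"spec{len(specimens) + 1}"
        specimens.append(SpecimenConfig(id=spec_id, coords=coords, scale=scale, image_ref=image_ref))
        curve_layouts.append((n_fixed, [len(c) for c in curves]))

    if not specimens:
        raise TPSParseError(f"{path}: no LM= records found")
    if len({tuple([nf] + cs) for nf, cs in curve_layouts}) != 1:
        raise TPSParseError(f"{path}: records disagree on landmark/curve layout")

    n_fixed, curve_counts = curve_layouts[0]
    sliders = _sliders_from_layout(n_fixed, curve_counts, curve_anchors)
    return LandmarkDataset(specimens, sliders=sliders)


def _sliders_from_layout(
    n_fixed: int,
    curve_counts: list[int],
    curve_anchors: Sequence[tuple[int, int]] | None,
) -> SliderTable:
    if not curve_counts:
        return SliderTable(np.empty((0, 3), int))
    spans = []
    start = n_fixed
    for c in curve_counts:
        spans.append(range(start, start + c))
        start += c
    if curve_anchors is not None:
        if len(curve_anchors) != len(curve_counts):
            raise ValueError("need one (before, after) anchor pair per curve")
        return make_sliders_from_curves(spans, curve_anchors)
    # endpoints of each curve act as that curve's anchors: interior points slide
    rows = []
    for span in spans:
        idx = list(span)
        for j in range(1, len(idx) - 1):
            rows.append((idx[j - 1], idx[j], idx[j + 1]))
    return SliderTable(np.asarray(rows, int).reshape(-1, 3))


def make_sliders_from_curves(
    curve_point_spans: Sequence[Sequence[int]],
    anchors: Sequence[tuple[int, int]],
) -> SliderTable:
    """Build a slider table from curves of semilandmarks.

    Each curve is a span of landmark indices (in order along the curve), all
    of which slide; ``anchors[c]`` gives the fixed landmarks bracketing curve
    c.  Interior semilandmarks slide between their curve neighbours, the
    first and last between the anchor and their single curve neighbour.
    """
    if len(anchors) != len(curve_point_spans):
        raise ValueError("need one anchor pair per curve")
    rows = []
    for span, (before_anchor, after_anchor) in zip(curve_point_spans, anchors):
        idx = list(span)
        if len(idx) == 0:
            raise ValueError("curve with no sliding points")
        chain = [before_anchor] + idx + [after_anchor]
        for j in range(1, len(chain) - 1):
            rows.append((chain[j - 1], chain[j], chain[j + 1]))
    return SliderTable(np.asarray(rows, int))


def write_tps(dataset: LandmarkDataset, path: str | Path, curve_counts: Sequence[int] | None = None) -> None:
    """Write a dataset as a TPS file.

    Coordinates are emitted with 17 significant digits so that a read/write
    round trip is lossless at double precision.  When ``curve_counts`` is
    given, that many trailing landmarks per specimen are emitted as
    ``CURVES``/``POINTS`` blocks; otherwise all points go under ``LM=``.
    """
    if dataset.n == 0:
        raise ValueError("refusing to write an empty dataset")
    path = Path(path)
    k = dataset.k
    counts = list(curve_counts) if curve_counts else []
    n_curve_pts = sum(counts)
    if n_curve_pts >= k:
        raise ValueError("curve points cannot exceed total landmarks")
    n_fixed = k - n_curve_pts

    def fmt(pt: np.ndarray) -> str:
        return f"{pt[0]:.17g} {pt[1]:.17g}"

    out = []
    for spec in dataset.specimens:
        out.append(f"LM={n_fixed}")
        out.extend(fmt(p) for p in spec.coords[:n_fixed])
        if counts:
            out.append(f"CURVES={len(counts)}")
            start = n_fixed
            for c in counts:
                out.append(f"POINTS={c}")
                out.extend(fmt(p) for p in spec.coords[start : start + c])
                start += c
        if spec.image_ref is not None:
            out.append(f"IMAGE={spec.image_ref}")
        out.append(f"ID={spec.id}")
        # SCALE already folded into coords on read; do not re-emit
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Side tables
# ---------------------------------------------------------------------------

def read_sliders_csv(path: str | Path) -> SliderTable:
    """Read a 3-column slider CSV (headers before,slide,after; 1-based)."""
    df = pd.read_csv(path)
    need = ["before", "slide", "after"]
    if list(df.columns[:3]) != need:
        raise ValueError(f"slider CSV must have columns {need}, got {list(df.columns)}")
    return SliderTable(df[need].to_numpy(dtype=int) - 1)


def write_sliders_csv(sliders: SliderTable, path: str | Path) -> None:
    df = pd.DataFrame(sliders.rows + 1, columns=["before", "slide", "after"])
    df.to_csv(path, index=False)


def read_classifiers_csv(path: str | Path) -> pd.DataFrame:
    """Read a classifier CSV; requires id,species,sex,view columns."""
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in REQUIRED_CLASSIFIER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"classifier CSV missing columns: {missing}")
    return df
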