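"""Reading and writing TPS landmark files and building fixed landmark configurations.

The TPS dialect handled here is the one emitted by tpsUtil/tpsDig: records
introduced by ``LM=n`` followed by ``n`` whitespace-separated coordinate
pairs, optionally followed by ``CURVES=c`` with per-curve ``POINTS=k``
blocks, and trailing ``IMAGE=``, ``ID=`` and ``SCALE=`` keys.  Coordinates
are kept exactly as stored (tpsDig's lower-left image origin included); an
optional ``flip_y`` negates y for callers that need image-row convention,
and ``apply_scale`` multiplies coordinates by the SCALE factor.

A specimen digitised as 5 fixed landmarks plus one head-outline curve is
turned into the analysis configuration by resampling the curve into equally
arc-length-spaced semilandmarks and merging curve endpoints that coincide
with fixed landmarks; the default scheme (5 fixed + 10 curve points with 2
endpoint merges) yields a 13-point configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "LandmarkSpecimen",
    "Configuration",
    "TPSParseError",
    "ConfigurationError",
    "DegenerateCurveError",
    "read_tps",
    "write_tps",
    "resample_curve",
    "build_configuration",
    "write_configurations_tsv",
]


class TPSParseError(ValueError):
    """Raised when a TPS file violates the LM=/CURVES=/POINTS= record grammar."""


class ConfigurationError(ValueError):
    """Raised when curve-endpoint merging does not produce the expected landmark count."""


class DegenerateCurveError(ValueError):
    """Raised when a polyline has zero total arc length."""


@dataclass
class LandmarkSpecimen:
    """One digitised specimen: ordered landmarks, optional curves and labels.

    ``labels`` carries sex (``F``/``M``), cox1 and morphological species
    calls and the sampling region when known.
    """

    specimen_id: str
    landmarks: np.ndarray  # (k, 2)
    curves: list[np.ndarray] = field(default_factory=list)  # each (m, 2), m >= 2
    scale: float | None = None
    image_ref: str | None = None
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.landmarks = np.asarray(self.landmarks, dtype=float)
        if self.landmarks.ndim != 2 or self.landmarks.shape[1] != 2:
            raise ValueError("landmarks must be an (k, 2) array")
        if len(self.landmarks) == 0:
            raise ValueError("landmark list must be non-empty")
        if not np.all(np.isfinite(self.landmarks)):
            raise ValueError("landmark coordinates must be finite")
        self.curves = [np.asarray(c, dtype=float) for c in self.curves]
        for c in self.curves:
            if c.ndim != 2 or c.shape[1] != 2 or len(c) < 2:
                raise ValueError("each curve needs >= 2 two-dimensional points")
            if not np.all(np.isfinite(c)):
                raise ValueError("curve coordinates must be finite")
        if self.scale is not None and not self.scale > 0:
            raise ValueError("scale must be positive when present")

    def __eq__(self, other: object) -> bool:  # value semantics for round-trip tests
        if not isinstance(other, LandmarkSpecimen):
            return NotImplemented
        return (
            self.specimen_id == other.specimen_id
            and np.array_equal(self.landmarks, other.landmarks)
            and len(self.curves) == len(other.curves)
            and all(np.array_equal(a, b) for a, b in zip(self.curves, other.curves))
            and self.scale == other.scale
            and self.image_ref == other.image_ref
        )


@dataclass
class Configuration:
    """A fixed-order point configuration ready for Procrustes analysis.

    ``provenance[i]`` is ``"fixed"`` for digitised landmarks and
    ``"semilandmark"`` for points obtained by curve resampling.
    """

    points: np.ndarray  # (p, 2)
    provenance: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be a (p, 2) array")
        if len(self.points) < 3:
            raise ValueError("a configuration needs p >= 3 points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("coordinates must be finite")

    @property
    def p(self) -> int:
        return len(self.points)


def _parse_coord_rows(lines: list[tuple[int, str]], start: int, count: int, record_index: int) -> tuple[np.ndarray, int]:
    pts = np.empty((count, 2), dtype=float)
    idx = start
    for i in range(count):
        if idx >= len(lines):
            raise TPSParseError(
                f"record {record_index}: expected {count} coordinate rows, file ended after {i}"
            )
        lineno, text = lines[idx]
        parts = text.split()
        if len(parts) != 2 or "=" in text:
            raise TPSParseError(
                f"record {record_index}: expected {count} coordinate rows, "
                f"found {i} before line {lineno}: {text!r}"
            )
        try:
            pts[i, 0] = float(parts[0])
            pts[i, 1] = float(parts[1])
        except ValueError as exc:
            raise TPSParseError(f"line {lineno}: non-numeric coordinate {text!r}") from exc
        idx += 1
    return pts, idx


def read_tps(
    path: str | Path,
    *,
    apply_scale: bool = False,
    flip_y: bool = False,
) -> list[LandmarkSpecimen]:
    """Parse a TPS file into a list of :class:`LandmarkSpecimen`.

    One specimen is produced per ``LM=`` record.  SCALE is stored on the
    specimen and only applied to coordinates when ``apply_scale`` is set;
    ``flip_y`` negates the y axis for image-convention files.
    """
    path = Path(path)
    raw = path.read_text().splitlines()
    lines = [(i + 1, ln.strip()) for i, ln in enumerate(raw) if ln.strip()]
    specimens: list[LandmarkSpecimen] = []
    idx = 0
    record_index = 0
    while idx < len(lines):
        lineno, text = lines[idx]
        key, _, value = text.partition("=")
        if key.strip().upper() != "LM":
            raise TPSParseError(f"line {lineno}: expected LM= record start, got {text!r}")
        try:
            n_lm = int(value)
        except ValueError as exc:
            raise TPSParseError(f"line {lineno}: bad landmark count {value!r}") from exc
        idx += 1
        landmarks, idx = _parse_coord_rows(lines, idx, n_lm, record_index)
        curves: list[np.ndarray] = []
        scale: float | None = None
        image_ref: str | None = None
        specimen_id: str | None = None
        while idx < len(lines):
            lineno, text = lines[idx]
            key, sep, value = text.partition("=")
            key = key.strip().upper()
            if not sep:
                raise TPSParseError(f"line {lineno}: unexpected content {text!r}")
            if key == "LM":
                break
            idx += 1
            if key == "CURVES":
                n_curves = int(value)
                for _ in range(n_curves):
                    if idx >= len(lines):
                        raise TPSParseError(f"record {record_index}: missing POINTS= block")
                    plineno, ptext = lines[idx]
                    pkey, _, pvalue = ptext.partition("=")
                    if pkey.strip().upper() != "POINTS":
                        raise TPSParseError(
                            f"line {plineno}: expected POINTS=, got {ptext!r}"
                        )
                    idx += 1
                    pts, idx = _parse_coord_rows(lines, idx, int(pvalue), record_index)
                    curves.append(pts)
            elif key == "IMAGE":
                image_ref = value.strip() or None
            elif key == "ID":
                specimen_id = value.strip()
            elif key == "SCALE":
                try:
                    scale = float(value)
                except ValueError as exc:
                    raise TPSParseError(f"line {lineno}: bad SCALE value {value!r}") from exc
            elif key == "COMMENT":
                continue
            else:
                raise TPSParseError(f"line {lineno}: unknown key {key!r}")
        if specimen_id is None:
            specimen_id = str(record_index)
        if apply_scale and scale is not None:
            landmarks = landmarks * scale
            curves = [c * scale for c in curves]
        if flip_y:
            landmarks = landmarks * np.array([1.0, -1.0])
            curves = [c * np.array([1.0, -1.0]) for c in curves]
        specimens.append(
            LandmarkSpecimen(
                specimen_id=specimen_id,
                landmarks=landmarks,
                curves=curves,
                scale=scale,
                image_ref=image_ref,
            )
        )
        record_index += 1
    return specimens


def _fmt(x: float) -> str:
    return repr(float(x))  # shortest exact round-trip decimal


def write_tps(specimens: Sequence[LandmarkSpecimen], path: str | Path) -> None:
    """Write specimens in TPS format parseable by :func:`read_tps`.

    Coordinates are formatted with 12 significant digits so that a
    read/write cycle is the identity on double-precision data to well
    below digitisation precision.
    """
    path = Path(path)
    out: list[str] = []
    for sp in specimens:
        out.append(f"LM={len(sp.landmarks)}")
        out.extend(f"{_fmt(x)} {_fmt(y)}" for x, y in sp.landmarks)
        if sp.curves:
            out.append(f"CURVES={len(sp.curves)}")
            for c in sp.curves:
                out.append(f"POINTS={len(c)}")
                out.extend(f"{_fmt(x)} {_fmt(y)}" for x, y in c)
        if sp.image_ref is not None:
            out.append(f"IMAGE={sp.image_ref}")
        out.append(f"ID={sp.specimen_id}")
        if sp.scale is not None:
            out.append(f"SCALE={_fmt(sp.scale)}")
    path.write_text("\n".join(out) + ("\n" if out else ""))


def resample_curve(polyline: np.ndarray, k: int) -> np.ndarray:
    """Resample an open polyline into ``k`` points equally spaced by arc length.

    The first and last output points are the polyline endpoints; consecutive
    outputs are separated by ``total_length / (k - 1)`` measured along the
    polyline.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("polyline must be an (m, 2) array with m >= 2")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0.0:
        raise DegenerateCurveError("polyline has zero total arc length")
    targets = np.linspace(0.0, total, k)
    # coordinates are piecewise-linear in arc length, so 1-D interpolation
    # per axis is the exact arc-length walk
    x = np.interp(targets, cum, pts[:, 0])
    y = np.interp(targets, cum, pts[:, 1])
    out = np.column_stack([x, y])
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


def build_configuration(
    specimen: LandmarkSpecimen,
    *,
    n_fixed: int = 5,
    curve_points: int = 10,
    merge_tolerance: float | None = None,
    expected_merges: int = 2,
    force: bool = False,
) -> Configuration:
    """Concatenate fixed landmarks with resampled curve semilandmarks.

    The first ``n_fixed`` landmarks are kept as digitised; the specimen's
    first curve is resampled into ``curve_points`` semilandmarks.  Curve
    endpoints within ``merge_tolerance`` of a fixed landmark are merged
    (the fixed landmark is kept), so the default scheme 5 + 10 with two
    endpoint merges produces 13 points.  A merge count different from
    ``expected_merges`` raises :class:`ConfigurationError` unless ``force``.

    ``merge_tolerance`` defaults to 1e-6 times the configuration diameter.
    """
    if len(specimen.landmarks) < n_fixed:
        raise ValueError(
            f"specimen {specimen.specimen_id!r} has {len(specimen.landmarks)} landmarks, "
            f"needs >= {n_fixed}"
        )
    if not specimen.curves:
        raise ValueError(f"specimen {specimen.specimen_id!r} has no curve to resample")
    fixed = specimen.landmarks[:n_fixed]
    semis = resample_curve(specimen.curves[0], curve_points)
    allpts = np.vstack([fixed, semis])
    if merge_tolerance is None:
        d = np.linalg.norm(allpts[:, None, :] - allpts[None, :, :], axis=-1)
        merge_tolerance = 1e-6 * float(d.max())
    merged_idx: list[int] = []
    for j in (0, curve_points - 1):  # only curve endpoints are merge candidates
        dist = np.linalg.norm(fixed - semis[j], axis=1)
        if dist.min() <= merge_tolerance:
            merged_idx.append(j)
    if len(merged_idx) != expected_merges and not force:
        raise ConfigurationError(
            f"specimen {specimen.specimen_id!r}: {len(merged_idx)} curve endpoints merged "
            f"with fixed landmarks, expected {expected_merges}"
        )
    keep = [j for j in range(curve_points) if j not in merged_idx]
    points = np.vstack([fixed, semis[keep]])
    provenance = {i: "fixed" for i in range(n_fixed)}
    provenance.update({n_fixed + i: "semilandmark" for i in range(len(keep))})
    return Configuration(points=points, provenance=provenance)


def write_configurations_tsv(
    configs: Sequence[Configuration],
    specimen_ids: Sequence[str],
    path: str | Path,
) -> None:
    """Export configurations as a long-format TSV (id, point index, x, y, provenance)."""
    lines = ["specimen_id\tpoint\tx\ty\tprovenance"]
    for sid, cfg in zip(specimen_ids, configs):
        for i, (x, y) in enumerate(cfg.points):
            prov = cfg.provenance.get(i, "fixed")
            lines.append(f"{sid}\t{i}\t{x:.10g}\t{y:.10g}\t{prov}")
    Path(path).write_text("\n".join(lines) + "\n")
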