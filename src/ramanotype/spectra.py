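"""Domain containers for Raman spectra and plain-CSV readers/writers.

A :class:`RamanSpectrum` is a single replicate scan (wavenumber axis +
intensity); a :class:`SpectraSet` is the n × p matrix every model in this
package consumes, with optional class labels and reference concentrations
(mg carotenoid / 100 g fruit) attached per row.

Files are wide CSV: first column ``wavenumber_cm-1``, one column per
sample/replicate, UTF-8, "." decimal.  Labels and concentrations travel in a
metadata sidecar CSV (columns ``sample_id``, ``class``,
``concentration_mg_per_100g``, ``analyte``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Closed vocabulary of the seven carotenoid-profile classes: high
#: all-trans-lycopene, lycopene + β-carotene, lycopene + γ-carotene,
#: β-carotene, β-carotene + anthocyanin, tetra-cis-lycopene ("tangerine"),
#: and low-carotenoid fruit.
CLASS_LABELS: tuple[str, ...] = (
    "lycopene_high",
    "lycopene_bcarotene",
    "lycopene_gcarotene",
    "bcarotene",
    "bcarotene_anthocyanin",
    "tetracis_lycopene",
    "low_carotenoid",
)


class SpectraFormatError(ValueError):
    """Raised for unparseable or ragged spectra files."""


class AxisError(ValueError):
    """Raised when a wavenumber axis is not strictly increasing or mismatched."""


def _validate_axis(axis: np.ndarray) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1:
        raise AxisError("axis must be one-dimensional")
    if not np.all(np.isfinite(axis)):
        raise AxisError("axis contains non-finite values")
    if axis.size >= 2 and not np.all(np.diff(axis) > 0):
        raise AxisError("wavenumber axis must be strictly increasing")
    return axis


@dataclass
class RamanSpectrum:
    """One replicate scan: wavenumbers (cm⁻¹, strictly increasing) + counts."""

    axis: np.ndarray
    intensity: np.ndarray
    sample_id: str
    replicate: int = 1

    def __post_init__(self) -> None:
        self.axis = _validate_axis(self.axis)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != self.axis.shape:
            raise ValueError(
                f"axis ({self.axis.size}) and intensity ({self.intensity.size}) "
                "lengths differ"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity contains non-finite values")
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")


@dataclass
class SpectraSet:
    """n_samples × p_wavenumbers intensity block with shared axis.

    ``labels`` (class name per row) and ``y`` (reference concentration per
    row, mg/100 g, nonnegative) are optional; ``meta`` holds the sample ids.
    """

    X: np.ndarray
    axis: np.ndarray
    meta: list[str] = field(default_factory=list)
    labels: np.ndarray | None = None
    y: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.axis = _validate_axis(self.axis)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.size and self.X.shape[1] != self.axis.size:
            raise AxisError(
                f"X has {self.X.shape[1]} columns but axis has {self.axis.size} points"
            )
        n = self.X.shape[0] if self.X.size else 0
        if not self.meta:
            self.meta = [f"s{i:03d}" for i in range(n)]
        if len(self.meta) != n:
            raise ValueError("meta length must equal number of rows")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.size != n:
                raise ValueError("labels length must equal number of rows")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)
            if self.y.size != n:
                raise ValueError("y length must equal number of rows")
            if np.any(self.y < 0):
                raise ValueError("reference concentrations must be >= 0")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0] if self.X.size else 0

    @property
    def n_wavenumbers(self) -> int:
        return self.axis.size

    def subset(self, idx: Sequence[int] | np.ndarray) -> "SpectraSet":
        idx = np.asarray(idx, dtype=int)
        return SpectraSet(
            X=self.X[idx],
            axis=self.axis,
            meta=[self.meta[i] for i in idx],
            labels=None if self.labels is None else self.labels[idx],
            y=None if self.y is None else self.y[idx],
        )


def _meta_path(path: Path) -> Path:
    return path.with_name(path.stem + "_meta.csv")


def write_spectra(spectra_set: SpectraSet, path: str | Path) -> Path:
    """Write a :class:`SpectraSet` as wide CSV plus a metadata sidecar.

    Column order is deterministic: ``wavenumber_cm-1`` first, then samples in
    their row order by id.
    """
    path = Path(path)
    cols = {"wavenumber_cm-1": spectra_set.axis}
    for i, sid in enumerate(spectra_set.meta):
        cols[sid] = spectra_set.X[i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")

    meta = pd.DataFrame(
        {
            "sample_id": spectra_set.meta,
            "class": (
                spectra_set.labels
                if spectra_set.labels is not None
                else [""] * spectra_set.n_samples
            ),
            "concentration_mg_per_100g": (
                spectra_set.y
                if spectra_set.y is not None
                else [np.nan] * spectra_set.n_samples
            ),
        }
    )
    meta.to_csv(_meta_path(path), index=False, float_format="%.12g")
    return path


def read_spectra(path: str | Path, layout: str = "wide") -> SpectraSet:
    """Read a spectra CSV written by :func:`write_spectra`.

    ``layout="wide"``: first column is the shared axis, remaining columns are
    samples.  ``layout="long"``: columns ``sample_id``, ``wavenumber_cm-1``,
    ``intensity``.  The metadata sidecar is picked up when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise SpectraFormatError(f"cannot parse {path}: {exc}") from exc

    if layout == "wide":
        axis = df.iloc[:, 0].to_numpy(dtype=float)
        order = np.argsort(axis, kind="stable")
        axis_sorted = axis[order]
        if np.any(np.diff(axis_sorted) <= 0):
            raise AxisError("duplicate or non-monotone wavenumbers in axis column")
        sample_ids = list(df.columns[1:])
        X = df.iloc[:, 1:].to_numpy(dtype=float).T[:, order]
    elif layout == "long":
        required = {"sample_id", "wavenumber_cm-1", "intensity"}
        if not required.issubset(df.columns):
            raise SpectraFormatError(f"long layout needs columns {sorted(required)}")
        wide = df.pivot(index="wavenumber_cm-1", columns="sample_id", values="intensity")
        if wide.isna().any().any():
            raise SpectraFormatError("ragged long-format file: missing grid points")
        axis_sorted = wide.index.to_numpy(dtype=float)
        _validate_axis(axis_sorted)
        sample_ids = [str(c) for c in wide.columns]
        X = wide.to_numpy(dtype=float).T
    else:
        raise ValueError(f"unknown layout {layout!r}")

    labels = y = None
    mpath = _meta_path(path)
    if mpath.exists():
        meta = pd.read_csv(mpath).set_index("sample_id").reindex(sample_ids)
        if "class" in meta and meta["class"].notna().any():
            labels = meta["class"].to_numpy(dtype=object)
        conc = meta.get("concentration_mg_per_100g")
        if conc is not None and conc.notna().any():
            y = conc.to_numpy(dtype=float)
    return SpectraSet(X=X, axis=axis_sorted, meta=sample_ids, labels=labels, y=y)


def average_replicates(spectra: Iterable[RamanSpectrum]) -> SpectraSet:
    """Collapse replicate scans to one row per sample_id (arithmetic mean).

    Replicate spectra of a sample must share the axis exactly.  Sample order
    follows first appearance.
    """
    groups: dict[str, list[RamanSpectrum]] = {}
    for s in spectra:
        groups.setdefault(s.sample_id, []).append(s)
    if not groups:
        raise ValueError("no spectra to average")

    first = next(iter(groups.values()))[0]
    axis = first.axis
    rows, ids = [], []
    for sid, reps in groups.items():
        for r in reps:
            if r.axis.shape != axis.shape or not np.array_equal(r.axis, axis):
                raise AxisError(f"replicate axes differ for sample {sid!r}")
        rows.append(np.mean([r.intensity for r in reps], axis=0))
        ids.append(sid)
    return SpectraSet(X=np.vstack(rows), axis=axis, meta=ids)
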