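"""Data model and I/O for covered-codend catch-at-length experiments.

A covered-codend experiment measures, for every haul and 1-cm length class,
how many fish were retained in the codend and how many escaped into the
fine-mesh cover.  Because large catches are subsampled on deck, each
compartment carries a subsampling ratio ``q`` in (0, 1]; counts are raised
by ``1/q`` in the selectivity likelihood.

Length classes are 1-cm bins labelled by their integer midpoint, fixed
package-wide (fork lengths are measured to the nearest centimetre).
Subsampling ratios apply at the haul x compartment level, not per class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "HaulRecord",
    "CatchDataset",
    "read_catch_table",
    "write_catch_table",
    "count_measured",
    "summarize_meta",
    "load_sea_trial_hauls",
    "load_sea_trial_oscillations",
    "load_flume_moving_angles",
]

REQUIRED_COLUMNS = (
    "haul_id",
    "treatment",
    "length_cm",
    "n_codend",
    "n_cover",
    "q_codend",
    "q_cover",
)

META_COLUMNS = ("duration_min", "depth_m", "speed_kt", "date")


class SchemaError(ValueError):
    """The input table does not have the expected columns/shape."""


class ValidationError(ValueError):
    """The input table has the right shape but invalid values."""


@dataclass
class HaulRecord:
    """Catch-at-length counts for one haul.

    Parameters
    ----------
    haul_id : str
        Unique haul identifier.
    treatment : str
        Gear treatment label (e.g. ``"shaking"``, ``"T90"``).
    length_classes : ndarray of int
        Strictly increasing 1-cm bin midpoints (cm).
    n_codend, n_cover : ndarray of int
        Fish measured per class in the codend (retained) and the cover
        (escaped).  These are *measured* counts, before raising by 1/q.
    q_codend, q_cover : float
        Compartment subsampling ratios in (0, 1].
    meta : dict
        Optional haul metadata (duration_min, depth_m, speed_kt, date).
    """

    haul_id: str
    treatment: str
    length_classes: np.ndarray
    n_codend: np.ndarray
    n_cover: np.ndarray
    q_codend: float
    q_cover: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.length_classes = np.asarray(self.length_classes)
        self.n_codend = np.asarray(self.n_codend)
        self.n_cover = np.asarray(self.n_cover)
        self.validate()

    def validate(self) -> None:
        if not (0.0 < self.q_codend <= 1.0):
            raise ValidationError(
                f"haul {self.haul_id}: q_codend={self.q_codend} outside (0, 1]"
            )
        if not (0.0 < self.q_cover <= 1.0):
            raise ValidationError(
                f"haul {self.haul_id}: q_cover={self.q_cover} outside (0, 1]"
            )
        if self.length_classes.ndim != 1 or np.any(np.diff(self.length_classes) <= 0):
            raise ValidationError(
                f"haul {self.haul_id}: length classes must be strictly increasing"
            )
        for name, arr in (("n_codend", self.n_codend), ("n_cover", self.n_cover)):
            if arr.shape != self.length_classes.shape:
                raise ValidationError(f"haul {self.haul_id}: {name} shape mismatch")
            if np.any(arr < 0) or not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValidationError(
                    f"haul {self.haul_id}: {name} must be non-negative integers"
                )
        if int(self.n_codend.sum() + self.n_cover.sum()) == 0:
            raise ValidationError(f"haul {self.haul_id}: no fish measured")

    # raised (per-haul) counts used by the likelihood
    @property
    def raised_codend(self) -> np.ndarray:
        return self.n_codend / self.q_codend

    @property
    def raised_cover(self) -> np.ndarray:
        return self.n_cover / self.q_cover

    def total_measured(self) -> int:
        return int(self.n_codend.sum() + self.n_cover.sum())


@dataclass
class CatchDataset:
    """A collection of hauls sharing the 1-cm binning convention.

    On construction the hauls are aligned to the union of their length
    classes, with absent classes zero-filled (zero counts add nothing to
    the likelihood, so alignment is free).
    """

    hauls: list[HaulRecord]

    def __post_init__(self) -> None:
        if not self.hauls:
            raise ValidationError("dataset has no hauls")
        ids = [h.haul_id for h in self.hauls]
        if len(set(ids)) != len(ids):
            raise ValidationError("haul_ids are not unique")
        self._align_classes()

    def _align_classes(self) -> None:
        lo = min(int(h.length_classes.min()) for h in self.hauls)
        hi = max(int(h.length_classes.max()) for h in self.hauls)
        union = np.arange(lo, hi + 1)
        for h in self.hauls:
            if h.length_classes.shape == union.shape and np.array_equal(
                h.length_classes, union
            ):
                continue
            nR = np.zeros(union.shape, dtype=h.n_codend.dtype)
            nE = np.zeros(union.shape, dtype=h.n_cover.dtype)
            idx = h.length_classes.astype(int) - lo
            nR[idx] = h.n_codend
            nE[idx] = h.n_cover
            h.length_classes, h.n_codend, h.n_cover = union.copy(), nR, nE

    @property
    def length_classes(self) -> np.ndarray:
        return self.hauls[0].length_classes

    @property
    def treatments(self) -> list[str]:
        seen: dict[str, None] = {}
        for h in self.hauls:
            seen.setdefault(h.treatment, None)
        return list(seen)

    def subset(self, treatment: str) -> "CatchDataset":
        if treatment not in self.treatments:
            raise KeyError(f"unknown treatment {treatment!r}")
        return CatchDataset([h for h in self.hauls if h.treatment == treatment])

    def pooled_raised(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (lengths, raised codend counts, raised cover counts) pooled over hauls."""
        nR = np.zeros(len(self.length_classes))
        nE = np.zeros(len(self.length_classes))
        for h in self.hauls:
            nR += h.raised_codend
            nE += h.raised_cover
        return self.length_classes.astype(float), nR, nE

    def __len__(self) -> int:
        return len(self.hauls)

    def __iter__(self):
        return iter(self.hauls)


def read_catch_table(
    path, schema: Mapping[str, str] | None = None
) -> CatchDataset:
    """Read a long-format catch table (one row per haul x length class).

    Parameters
    ----------
    path : path or file-like
        CSV with columns ``haul_id, treatment, length_cm, n_codend,
        n_cover, q_codend, q_cover`` plus optional metadata columns.
    schema : mapping, optional
        Renames file columns to the canonical names, e.g.
        ``{"tow": "haul_id"}``.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty catch table: {path}") from exc
    if schema:
        df = df.rename(columns=dict(schema))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    if len(df) == 0:
        raise SchemaError("catch table has no rows")
    return _dataset_from_frame(df)


def _dataset_from_frame(df: pd.DataFrame) -> CatchDataset:
    hauls = []
    for haul_id, grp in df.groupby("haul_id", sort=False):
        treatments = grp["treatment"].unique()
        if len(treatments) != 1:
            raise ValidationError(f"haul {haul_id}: multiple treatment labels")
        for qcol in ("q_codend", "q_cover"):
            if grp[qcol].nunique() != 1:
                raise ValidationError(f"haul {haul_id}: {qcol} varies within haul")
        order = np.argsort(grp["length_cm"].to_numpy())
        lengths = grp["length_cm"].to_numpy()[order]
        counts_R = grp["n_codend"].to_numpy()[order]
        counts_E = grp["n_cover"].to_numpy()[order]
        if np.any(counts_R != counts_R.astype(int)) or np.any(
            counts_E != counts_E.astype(int)
        ):
            raise ValidationError(f"haul {haul_id}: non-integer counts")
        meta = {}
        for c in META_COLUMNS:
            if c in grp.columns:
                meta[c] = grp[c].iloc[0]
        hauls.append(
            HaulRecord(
                haul_id=str(haul_id),
                treatment=str(treatments[0]),
                length_classes=lengths.astype(int),
                n_codend=counts_R.astype(int),
                n_cover=counts_E.astype(int),
                q_codend=float(grp["q_codend"].iloc[0]),
                q_cover=float(grp["q_cover"].iloc[0]),
                meta=meta,
            )
        )
    return CatchDataset(hauls)


def to_frame(dataset: CatchDataset) -> pd.DataFrame:
    rows = []
    for h in dataset:
        for l, nR, nE in zip(h.length_classes, h.n_codend, h.n_cover):
            row = {
                "haul_id": h.haul_id,
                "treatment": h.treatment,
                "length_cm": int(l),
                "n_codend": int(nR),
                "n_cover": int(nE),
                "q_codend": h.q_codend,
                "q_cover": h.q_cover,
            }
            row.update(h.meta)
            rows.append(row)
    return pd.DataFrame(rows)


def write_catch_table(dataset: CatchDataset, path) -> None:
    """Write a dataset back to the long-format CSV dialect it is read from."""
    to_frame(dataset).to_csv(path, index=False)


def count_measured(dataset: CatchDataset, treatment: str) -> int:
    """Total fish measured (codend + cover, unraised) for a treatment."""
    if treatment not in dataset.treatments:
        raise KeyError(f"unknown treatment {treatment!r}")
    return sum(h.total_measured() for h in dataset if h.treatment == treatment)


def summarize_meta(dataset: CatchDataset, field_name: str) -> dict:
    """Mean, sample SD (n-1), min and max of a numeric haul metadata field."""
    values = []
    for h in dataset:
        if field_name not in h.meta:
            raise KeyError(f"haul {h.haul_id} lacks metadata field {field_name!r}")
        v = h.meta[field_name]
        if not np.isreal(v) or isinstance(v, (str, bytes)):
            raise ValidationError(f"metadata field {field_name!r} is not numeric")
        values.append(float(v))
    arr = np.asarray(values)
    return {
        "n": len(arr),
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if len(arr) > 1 else None,
        "min": float(arr.min()),
        "max": float(arr.max()),
    }


def summary_json(dataset: CatchDataset, fields: Iterable[str]) -> str:
    out = {
        "treatments": {
            t: count_measured(dataset, t) for t in dataset.treatments
        },
        "meta": {f: summarize_meta(dataset, f) for f in fields},
    }
    return json.dumps(out, indent=2)


# ---------------------------------------------------------------------------
# Bundled sea-trial tables (published operational summaries; small, text-only)
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("trawlsel").joinpath("data", name)


def load_sea_trial_hauls() -> CatchDataset:
    """Sea-trial haul log: 15 hauls (4 shaking, 11 T90).

    The published log records per-haul measured totals, subsampling ratios
    and operating conditions but no per-length-class frequencies, so each
    haul's totals are collapsed into a single length bin.  Suitable for
    catch bookkeeping and metadata summaries, not for selectivity fitting.
    """
    with _data_path("sea_trial_hauls.csv").open() as fh:
        return read_catch_table(fh)


def load_sea_trial_oscillations() -> pd.DataFrame:
    """At-sea codend oscillation subsamples: amplitude ratio and period per
    stable-depth subsample (9 subsamples over three hauls)."""
    with _data_path("sea_trial_oscillations.csv").open() as fh:
        return pd.read_csv(fh)


def load_flume_moving_angles() -> pd.DataFrame:
    """Mean codend moving angle (deg) per flume-tank flow velocity (kt)."""
    with _data_path("flume_moving_angle.csv").open() as fh:
        return pd.read_csv(fh)
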