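"""Biopsy cohort representation and pairwise Euclidean distances.

A multi-site biopsy cohort consists of physically localized tissue samples,
each with stereotactic image coordinates in mm. Needle cores may be divided
into a "shallow" and a "deep" sub-sample along the needle track; such a
split pair is assigned a fixed geometric offset (5 mm by default, from the
needle side-port geometry) instead of a coordinate-derived distance. All
distances are intra-patient: samples are never compared across tumors.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

INSTRUMENTS = ("needle", "forceps")
DEPTH_LABELS = ("shallow", "deep", "whole")
PAIR_KINDS = ("coordinate", "shallow_deep_needle", "same_site_forceps")


@dataclass(frozen=True)
class BiopsySite:
    """A physically localized tissue sample.

    Coordinates are in mm in the image frame; they may be absent (``None``
    as a triple) when the imaging coordinates were ambiguous or not
    recorded. ``source_site_id`` identifies the physical needle track or
    forceps location; a shallow/deep split pair shares it.
    """

    patient_id: str
    sample_id: str
    x: float | None = None
    y: float | None = None
    z: float | None = None
    instrument: str = "needle"
    depth_label: str = "whole"
    source_site_id: str | None = None

    def __post_init__(self) -> None:
        if self.instrument not in INSTRUMENTS:
            raise ValueError(
                f"sample {self.sample_id}: instrument must be one of {INSTRUMENTS}, "
                f"got {self.instrument!r}"
            )
        if self.depth_label not in DEPTH_LABELS:
            raise ValueError(
                f"sample {self.sample_id}: depth_label must be one of {DEPTH_LABELS}, "
                f"got {self.depth_label!r}"
            )
        coords = (self.x, self.y, self.z)
        n_missing = sum(c is None for c in coords)
        if n_missing not in (0, 3):
            # partial triples are not repaired: the site is flagged coordinate-less
            logger.warning(
                "sample %s/%s has a partial coordinate triple %s; treated as "
                "coordinate-less",
                self.patient_id,
                self.sample_id,
                coords,
            )
            object.__setattr__(self, "x", None)
            object.__setattr__(self, "y", None)
            object.__setattr__(self, "z", None)
        elif n_missing == 0:
            for name, c in zip("xyz", coords):
                if not math.isfinite(c):
                    raise ValueError(
                        f"sample {self.sample_id}: non-finite coordinate {name}={c}"
                    )

    @property
    def has_coordinates(self) -> bool:
        return self.x is not None

    @property
    def coordinates(self) -> tuple[float, float, float]:
        if not self.has_coordinates:
            raise ValueError(f"sample {self.sample_id} has no coordinates")
        return (self.x, self.y, self.z)


@dataclass(frozen=True)
class SamplePair:
    """An unordered intra-patient sample pair with its Euclidean distance."""

    patient_id: str
    sample_a: str
    sample_b: str
    euclidean_mm: float
    pair_kind: str = "coordinate"

    def __post_init__(self) -> None:
        if self.sample_a == self.sample_b:
            raise ValueError(f"pair members must differ, got {self.sample_a!r} twice")
        if self.euclidean_mm < 0:
            raise ValueError(f"euclidean_mm must be >= 0, got {self.euclidean_mm}")
        if self.pair_kind not in PAIR_KINDS:
            raise ValueError(f"unknown pair_kind {self.pair_kind!r}")
        # canonical (sorted) member order so the pair is genuinely unordered
        if self.sample_a > self.sample_b:
            a, b = self.sample_a, self.sample_b
            object.__setattr__(self, "sample_a", b)
            object.__setattr__(self, "sample_b", a)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.patient_id, self.sample_a, self.sample_b)


@dataclass
class PairingConfig:
    """Options for pair enumeration.

    ``shallow_deep_mm`` is the fixed distance for a needle core divided into
    shallow/deep sub-samples (from the needle geometry). The distance for a
    shallow/deep pair taken with forceps at one spatial location is not
    geometrically constrained; 0 is the only coordinate-consistent default,
    and such pairs can be excluded from downstream association entirely.
    """

    shallow_deep_mm: float = 5.0
    same_site_forceps_mm: float = 0.0
    exclude_same_site_forceps: bool = False

    def __post_init__(self) -> None:
        if self.shallow_deep_mm < 0 or self.same_site_forceps_mm < 0:
            raise ValueError("configured pair distances must be non-negative")


def euclidean_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Euclidean distance between two 3D coordinate triples in mm.

    d = sqrt((x_a - x_b)^2 + (y_a - y_b)^2 + (z_a - z_b)^2)
    """
    if len(a) != 3 or len(b) != 3:
        raise ValueError("coordinates must be 3D triples")
    for triple in (a, b):
        for c in triple:
            if c is None or not math.isfinite(c):
                raise ValueError(f"non-finite coordinate in {tuple(triple)}")
    return math.dist(a, b)


def _is_shallow_deep_pair(s1: BiopsySite, s2: BiopsySite) -> bool:
    return (
        s1.source_site_id is not None
        and s1.source_site_id == s2.source_site_id
        and {s1.depth_label, s2.depth_label} == {"shallow", "deep"}
    )


def enumerate_pairs(
    sites: Iterable[BiopsySite], config: PairingConfig | None = None
) -> list[SamplePair]:
    """Enumerate every unordered intra-patient sample pair.

    Shallow/deep sub-samples of one needle track get the configured fixed
    distance (default 5 mm); shallow/deep forceps samples from one location
    get the configured same-site distance (default 0 mm). All other pairs
    use the Euclidean distance between their coordinates; samples without
    coordinates are excluded from coordinate pairs and counted in the log.
    """
    config = config or PairingConfig()
    by_patient: dict[str, list[BiopsySite]] = {}
    for s in sites:
        patient = by_patient.setdefault(s.patient_id, [])
        if any(existing.sample_id == s.sample_id for existing in patient):
            raise ValueError(
                f"duplicate sample_id {s.sample_id!r} within patient {s.patient_id!r}"
            )
        patient.append(s)

    pairs: list[SamplePair] = []
    n_skipped_missing = 0
    for patient_id in sorted(by_patient):
        patient_sites = sorted(by_patient[patient_id], key=lambda s: s.sample_id)
        for s1, s2 in itertools.combinations(patient_sites, 2):
            if _is_shallow_deep_pair(s1, s2):
                if s1.instrument == "forceps" or s2.instrument == "forceps":
                    if config.exclude_same_site_forceps:
                        continue
                    kind, dist = "same_site_forceps", config.same_site_forceps_mm
                else:
                    kind, dist = "shallow_deep_needle", config.shallow_deep_mm
            else:
                if not (s1.has_coordinates and s2.has_coordinates):
                    n_skipped_missing += 1
                    continue
                kind = "coordinate"
                dist = euclidean_distance(s1.coordinates, s2.coordinates)
            pairs.append(
                SamplePair(patient_id, s1.sample_id, s2.sample_id, dist, kind)
            )
    if n_skipped_missing:
        logger.info(
            "enumerate_pairs: %d candidate pairs skipped for missing coordinates",
            n_skipped_missing,
        )
    return pairs


DEFAULT_COLUMNS = {
    "patient_id": "patient_id",
    "sample_id": "sample_id",
    "x": "x_mm",
    "y": "y_mm",
    "z": "z_mm",
    "instrument": "instrument",
    "depth_label": "depth_label",
    "source_site_id": "source_site_id",
}


def read_coordinates(
    path, column_map: dict[str, str] | None = None
) -> list[BiopsySite]:
    """Read biopsy sites from a delimited table (TSV or CSV).

    The header must name at least the patient, sample and x/y/z columns
    (default names ``patient_id, sample_id, x_mm, y_mm, z_mm``; override via
    ``column_map`` keyed by field name). Instrument/depth/source columns are
    optional. Rows with an empty coordinate triple are kept and flagged
    coordinate-less.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    mandatory = ["patient_id", "sample_id", "x", "y", "z"]
    missing = [cols[f] for f in mandatory if cols[f] not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")

    sites: list[BiopsySite] = []
    seen: set[tuple[str, str]] = set()
    for idx, row in df.iterrows():
        rownum = idx + 2  # 1-based with header line
        patient_id = str(row[cols["patient_id"]]).strip()
        sample_id = str(row[cols["sample_id"]]).strip()
        if (patient_id, sample_id) in seen:
            raise ValueError(
                f"{path}: duplicated (patient, sample) ({patient_id}, {sample_id}) "
                f"at row {rownum}"
            )
        seen.add((patient_id, sample_id))
        coords = []
        for f in ("x", "y", "z"):
            raw = row[cols[f]]
            if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip() == "":
                coords.append(None)
                continue
            try:
                coords.append(float(raw))
            except ValueError as exc:
                raise ValueError(
                    f"{path}: unparsable {f} value {raw!r} at row {rownum}"
                ) from exc

        def _opt(fname: str, default: str | None) -> str | None:
            col = cols[fname]
            if col not in df.columns:
                return default
            raw = row[col]
            if raw is None or (isinstance(raw, float) and math.isnan(raw)):
                return default
            text = str(raw).strip()
            return text if text else default

        sites.append(
            BiopsySite(
                patient_id=patient_id,
                sample_id=sample_id,
                x=coords[0],
                y=coords[1],
                z=coords[2],
                instrument=_opt("instrument", "needle"),
                depth_label=_opt("depth_label", "whole"),
                source_site_id=_opt("source_site_id", None),
            )
        )
    return sites


def pairs_to_frame(pairs: Iterable[SamplePair]) -> pd.DataFrame:
    """Tabulate pairs as a DataFrame with fixed column order."""
    return pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "sample_a": p.sample_a,
                "sample_b": p.sample_b,
                "euclidean_mm": p.euclidean_mm,
                "pair_kind": p.pair_kind,
            }
            for p in pairs
        ],
        columns=["patient_id", "sample_a", "sample_b", "euclidean_mm", "pair_kind"],
    )


def write_pairs(pairs: Iterable[SamplePair], path) -> None:
    pairs_to_frame(pairs).to_csv(path, sep="\t", index=False, float_format="%.6g")
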