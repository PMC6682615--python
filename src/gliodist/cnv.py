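"""Copy-number segment unification and the Canberra CNV distance.

Each sample arrives with a non-overlapping segmentation (0-based, half-open
intervals; CNVkit ``.cns`` convention) carrying a log2 copy-ratio per
segment. Within a patient, all samples' breakpoints are pooled and the
coarsest common refinement defines a shared list of CNV "events"; each
event inherits the log2 of the unique source segment covering it, or is
marked absent where a sample's segmentation has no coverage. The distance
between two samples over their shared events is the Canberra distance

    d = sum_i |P_i - Q_i| / (|P_i| + |Q_i|),

with a 0/0 term defined as 0 so that self-distance is exactly zero. The
per-coordinate normalizer uses magnitudes because log2 ratios are signed
(losses negative, gains positive); on non-negative data this coincides
with the classical Canberra form.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CNVSegment:
    """One sample's copy-number segment (0-based start, exclusive end)."""

    patient_id: str
    sample_id: str
    chrom: str
    start: int
    end: int
    log2: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"{self.sample_id} {self.chrom}:{self.start}-{self.end}: "
                "start must be < end"
            )
        if not np.isfinite(self.log2):
            raise ValueError(
                f"{self.sample_id} {self.chrom}:{self.start}-{self.end}: "
                f"non-finite log2 {self.log2}"
            )


Event = tuple[str, int, int]


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Natural chromosome ordering: 1..22, X, Y, M, then others lexically."""
    name = re.sub("^chr", "", chrom)
    if name.isdigit():
        return (int(name), "")
    special = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    return (special.get(name, 26), name)


def _validate_sample_segments(segments: Sequence[CNVSegment]) -> None:
    by_key: dict[tuple[str, str], list[CNVSegment]] = {}
    for seg in segments:
        by_key.setdefault((seg.sample_id, seg.chrom), []).append(seg)
    for (sample, chrom), segs in by_key.items():
        segs = sorted(segs, key=lambda s: s.start)
        for prev, cur in zip(segs, segs[1:]):
            if cur.start < prev.end:
                raise ValueError(
                    f"sample {sample}: overlapping segments on {chrom}: "
                    f"[{prev.start}, {prev.end}) and [{cur.start}, {cur.end})"
                )


def union_breakpoints(segments: Sequence[CNVSegment]) -> list[Event]:
    """Coarsest common refinement of all samples' segmentations.

    Per chromosome, the sorted union of every start/end defines maximal
    intervals; intervals covered by at least one sample are returned as
    events, sorted by (chrom, start). Events never straddle any input
    breakpoint.
    """
    if not segments:
        return []
    _validate_sample_segments(segments)
    events: list[Event] = []
    by_chrom: dict[str, list[CNVSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom in sorted(by_chrom, key=chrom_sort_key):
        segs = by_chrom[chrom]
        bounds = sorted({b for s in segs for b in (s.start, s.end)})
        starts = np.array([s.start for s in segs])
        ends = np.array([s.end for s in segs])
        for lo, hi in zip(bounds, bounds[1:]):
            # candidate interval is covered iff contained in some segment
            if np.any((starts <= lo) & (ends >= hi)):
                events.append((chrom, lo, hi))
    return events


@dataclass
class CNVEventMatrix:
    """Unified event x sample log2 matrix with a presence mask.

    ``log2[e, s]`` is NaN where ``present[e, s]`` is False (the sample's
    segmentation does not cover that event).
    """

    patient_id: str
    events: list[Event]
    sample_ids: list[str]
    log2: np.ndarray
    present: np.ndarray

    def column(self, sample_id: str) -> tuple[np.ndarray, np.ndarray]:
        j = self.sample_ids.index(sample_id)
        return self.log2[:, j], self.present[:, j]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.log2,
            columns=self.sample_ids,
            index=pd.MultiIndex.from_tuples(self.events, names=["chrom", "start", "end"]),
        )
        return df.reset_index()


def build_event_matrix(
    events: Sequence[Event], segments: Sequence[CNVSegment]
) -> CNVEventMatrix:
    """Assign each sample's segment log2 values onto the unified events.

    No interpolation: an event is present for a sample only when one of the
    sample's segments fully contains it (guaranteed by construction when
    ``events`` came from :func:`union_breakpoints` over the same segments).
    """
    patients = {s.patient_id for s in segments}
    if len(patients) != 1:
        raise ValueError(f"segments span several patients: {sorted(patients)}")
    patient_id = patients.pop()
    sample_ids = sorted({s.sample_id for s in segments})
    sample_idx = {s: j for j, s in enumerate(sample_ids)}

    log2 = np.full((len(events), len(sample_ids)), np.nan)
    present = np.zeros((len(events), len(sample_ids)), dtype=bool)

    by_sample_chrom: dict[tuple[str, str], list[CNVSegment]] = {}
    for seg in segments:
        by_sample_chrom.setdefault((seg.sample_id, seg.chrom), []).append(seg)
    for segs in by_sample_chrom.values():
        segs.sort(key=lambda s: s.start)

    for e, (chrom, lo, hi) in enumerate(events):
        for sample, j in sample_idx.items():
            segs = by_sample_chrom.get((sample, chrom), [])
            for seg in segs:
                if seg.start <= lo and seg.end >= hi:
                    log2[e, j] = seg.log2
                    present[e, j] = True
                    break
                if seg.start < hi and seg.end > lo:
                    raise RuntimeError(
                        f"internal consistency error: event {chrom}:{lo}-{hi} "
                        f"partially covered by a segment of sample {sample}"
                    )
    return CNVEventMatrix(patient_id, list(events), sample_ids, log2, present)


def canberra_distance(
    P: Sequence[float], Q: Sequence[float], mask: Sequence[bool] | None = None
) -> float:
    """Canberra distance over the (optionally masked) shared events.

    Terms with |P_i| + |Q_i| = 0 contribute 0, so identical vectors —
    including all-zero ones — are at distance 0; every term lies in [0, 1],
    so the total is bounded by the number of contributing events.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"length mismatch: {P.shape} vs {Q.shape}")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != P.shape:
            raise ValueError("mask length must match vectors")
        P, Q = P[mask], Q[mask]
    denom = np.abs(P) + np.abs(Q)
    num = np.abs(P - Q)
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return float(terms.sum())


def cnv_pair_distances(
    m: CNVEventMatrix, impute_neutral: bool = False, drop_sex_chroms: bool = False
) -> pd.DataFrame:
    """All intra-patient pairwise Canberra distances over shared events.

    Events absent from either sample are excluded pairwise by default
    (pairwise-complete analysis); with ``impute_neutral`` absent events are
    instead treated as copy-neutral (log2 = 0), appropriate for
    whole-genome tilings where missing coverage means "no call".
    """
    keep = np.ones(len(m.events), dtype=bool)
    if drop_sex_chroms:
        sex = {"X", "Y", "chrX", "chrY"}
        keep = np.array([ev[0] not in sex for ev in m.events])
    rows = []
    for i, a in enumerate(m.sample_ids):
        for b in m.sample_ids[i + 1 :]:
            Pa, pa = m.column(a)
            Pb, pb = m.column(b)
            if impute_neutral:
                Pa = np.where(pa, Pa, 0.0)
                Pb = np.where(pb, Pb, 0.0)
                shared = keep.copy()
            else:
                shared = pa & pb & keep
            rows.append(
                {
                    "patient_id": m.patient_id,
                    "sample_a": a,
                    "sample_b": b,
                    "canberra_distance": canberra_distance(Pa, Pb, shared),
                    "n_events_shared": int(shared.sum()),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "sample_a", "sample_b", "canberra_distance", "n_events_shared"],
    )


CNS_COLUMN_ALIASES = {"chromosome": "chrom", "chrom": "chrom"}


def read_cns(path, sample_id: str, patient_id: str) -> list[CNVSegment]:
    """Read a CNVkit ``.cns``-style segment TSV.

    Requires at least ``chromosome, start, end, log2`` columns (extra
    CNVkit columns such as ``gene``, ``depth``, ``probes`` are ignored).
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    chrom_col = cols.get("chromosome") or cols.get("chrom")
    if chrom_col is None or not {"start", "end", "log2"} <= set(cols):
        raise ValueError(
            f"{path}: need columns chromosome/chrom, start, end, log2; got {list(df.columns)}"
        )
    return [
        CNVSegment(
            patient_id=patient_id,
            sample_id=sample_id,
            chrom=str(row[chrom_col]),
            start=int(row[cols["start"]]),
            end=int(row[cols["end"]]),
            log2=float(row[cols["log2"]]),
        )
        for _, row in df.iterrows()
    ]


def write_cns(segments: Iterable[CNVSegment], path) -> None:
    pd.DataFrame(
        [
            {"chromosome": s.chrom, "start": s.start, "end": s.end, "log2": s.log2}
            for s in segments
        ],
        columns=["chromosome", "start", "end", "log2"],
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
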