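"""Somatic mutation filtering, allele-frequency matrices and the Jaccard
(Tanimoto) mutation-count genetic distance.

Variant calls are filtered by five criteria — exonic location, a
protein-altering function class, reference read support >= 10, alternate
read support >= 8, and alternate allele frequency >= 0.1 — before being
assembled into a per-patient mutation x sample allele-frequency matrix.
The continuous Jaccard distance between two samples' AF vectors,

    d = sum_i (P_i - Q_i)^2 / (sum_i P_i^2 + sum_i Q_i^2 - sum_i P_i Q_i),

is 0 for identical profiles and 1 when the mutation sets are disjoint; on
presence/absence (binary) vectors it reduces to the set Jaccard distance
1 - |A & B| / |A | B|.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MutationKey = tuple[str, int, str, str]

DEFAULT_ALLOWED_REGIONS = frozenset({"exonic"})
DEFAULT_ALLOWED_FUNCTIONS = frozenset(
    {
        "frameshift deletion",
        "frameshift insertion",
        "nonsynonymous SNV",
        "stopgain",
        "stoploss",
    }
)


@dataclass
class VariantCall:
    """One annotated somatic variant call in one sample (1-based position)."""

    patient_id: str
    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str | None = None
    region_class: str = "exonic"
    func_class: str = "nonsynonymous SNV"
    ref_reads: int = 0
    alt_reads: int = 0
    alt_freq: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1 (1-based), got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ, got {self.ref!r}")
        if self.ref_reads < 0 or self.alt_reads < 0:
            raise ValueError("read counts must be non-negative")
        total = self.ref_reads + self.alt_reads
        if self.alt_freq is None:
            self.alt_freq = self.alt_reads / total if total > 0 else None
        elif total > 0:
            implied = self.alt_reads / total
            if abs(implied - self.alt_freq) > 1e-6:
                # provided value wins: counts may cover a different read subset
                warnings.warn(
                    f"{self.sample_id} {self.key}: alt_freq {self.alt_freq:.4g} "
                    f"inconsistent with read counts ({implied:.4g}); keeping the "
                    "provided value",
                    stacklevel=2,
                )
        if self.alt_freq is not None and not (0.0 <= self.alt_freq <= 1.0):
            raise ValueError(f"alt_freq must lie in [0, 1], got {self.alt_freq}")

    @property
    def key(self) -> MutationKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class MutationFilterConfig:
    """The five retention criteria applied to annotated calls."""

    allowed_regions: frozenset[str] = DEFAULT_ALLOWED_REGIONS
    allowed_functions: frozenset[str] = DEFAULT_ALLOWED_FUNCTIONS
    min_ref_reads: int = 10
    min_alt_reads: int = 8
    min_alt_freq: float = 0.1

    def __post_init__(self) -> None:
        if self.min_ref_reads < 0 or self.min_alt_reads < 0:
            raise ValueError("read-count thresholds must be non-negative")
        if not (0.0 <= self.min_alt_freq <= 1.0):
            raise ValueError("min_alt_freq must lie in [0, 1]")


CRITERIA = (
    "region_not_allowed",
    "function_not_allowed",
    "ref_reads_below_min",
    "alt_reads_below_min",
    "alt_freq_below_min",
)


def _violations(call: VariantCall, cfg: MutationFilterConfig) -> list[str]:
    v = []
    if call.region_class not in cfg.allowed_regions:
        v.append("region_not_allowed")
    if call.func_class not in cfg.allowed_functions:
        v.append("function_not_allowed")
    if call.ref_reads < cfg.min_ref_reads:
        v.append("ref_reads_below_min")
    if call.alt_reads < cfg.min_alt_reads:
        v.append("alt_reads_below_min")
    if call.alt_freq is None or call.alt_freq < cfg.min_alt_freq:
        v.append("alt_freq_below_min")
    return v


def filter_variants(
    calls: Iterable[VariantCall],
    cfg: MutationFilterConfig | None = None,
    return_tally: bool = False,
):
    """Retain exactly the calls passing all five criteria, preserving order.

    With ``return_tally=True`` also returns a Counter of rejection reasons
    (a call violating several criteria increments each).
    """
    cfg = cfg or MutationFilterConfig()
    kept: list[VariantCall] = []
    tally: Counter[str] = Counter()
    for call in calls:
        v = _violations(call, cfg)
        if v:
            tally.update(v)
        else:
            kept.append(call)
    logger.info("filter_variants: kept %d, rejections by criterion %s", len(kept), dict(tally))
    if return_tally:
        return kept, tally
    return kept


@dataclass
class MutationProfileMatrix:
    """Per-patient mutation x sample alternative-allele-frequency matrix.

    ``af[i, s]`` is the AF of mutation ``mutation_keys[i]`` in sample
    ``sample_ids[s]``, 0 where the sample lacks the call.
    """

    patient_id: str
    mutation_keys: list[MutationKey]
    sample_ids: list[str]
    af: np.ndarray

    def __post_init__(self) -> None:
        self.af = np.asarray(self.af, dtype=float)
        if self.af.shape != (len(self.mutation_keys), len(self.sample_ids)):
            raise ValueError("af shape must be (n_mutations, n_samples)")
        if self.af.size and (self.af.min() < 0 or self.af.max() > 1):
            raise ValueError("af values must lie in [0, 1]")

    def column(self, sample_id: str) -> np.ndarray:
        return self.af[:, self.sample_ids.index(sample_id)]


def build_af_matrix(calls: Sequence[VariantCall]) -> MutationProfileMatrix:
    """Assemble one patient's AF matrix from (typically filtered) calls.

    Mutation keys are the union over samples; absent calls get AF 0.
    Conflicting duplicate (key, sample) entries are an error.
    """
    if not calls:
        raise ValueError("no calls supplied")
    patients = {c.patient_id for c in calls}
    if len(patients) != 1:
        raise ValueError(f"calls span several patients: {sorted(patients)}")
    patient_id = patients.pop()

    sample_ids = sorted({c.sample_id for c in calls})
    keys = sorted({c.key for c in calls})
    key_idx = {k: i for i, k in enumerate(keys)}
    sample_idx = {s: j for j, s in enumerate(sample_ids)}

    af = np.zeros((len(keys), len(sample_ids)))
    seen: set[tuple[MutationKey, str]] = set()
    for c in calls:
        slot = (c.key, c.sample_id)
        if slot in seen:
            raise ValueError(
                f"duplicate call for mutation {c.key} in sample {c.sample_id}"
            )
        seen.add(slot)
        if c.alt_freq is None:
            raise ValueError(f"call {c.key} in {c.sample_id} has no usable alt_freq")
        af[key_idx[c.key], sample_idx[c.sample_id]] = c.alt_freq
    return MutationProfileMatrix(patient_id, keys, sample_ids, af)


def jaccard_distance(P: Sequence[float], Q: Sequence[float]) -> float:
    """Continuous Jaccard (Tanimoto) distance between two AF vectors.

    Defined as 0 when both vectors are all-zero (identical empty profiles);
    a warning is emitted since the ratio itself is 0/0 there.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"length mismatch: {P.shape} vs {Q.shape}")
    if P.size and (min(P.min(), Q.min()) < 0 or max(P.max(), Q.max()) > 1):
        raise ValueError("AF entries must lie in [0, 1]")
    denom = float(P @ P + Q @ Q - P @ Q)
    if denom == 0.0:
        warnings.warn(
            "jaccard_distance of two all-zero profiles is 0/0; defined as 0",
            stacklevel=2,
        )
        return 0.0
    diff = P - Q
    return float(diff @ diff) / denom


def mutation_pair_distances(m: MutationProfileMatrix) -> pd.DataFrame:
    """All intra-patient pairwise mutation distances.

    Returns one row per unordered sample pair with the continuous Jaccard
    distance, the union/shared mutation counts and the distinct-mutation
    count (``n_union - n_shared``, the symmetric difference) used for the
    count-scale spatial regression.
    """
    rows = []
    for i, a in enumerate(m.sample_ids):
        for b in m.sample_ids[i + 1 :]:
            P, Q = m.column(a), m.column(b)
            present_a, present_b = P > 0, Q > 0
            n_union = int((present_a | present_b).sum())
            n_shared = int((present_a & present_b).sum())
            rows.append(
                {
                    "patient_id": m.patient_id,
                    "sample_a": a,
                    "sample_b": b,
                    "jaccard_distance": jaccard_distance(P, Q),
                    "n_union_mutations": n_union,
                    "n_shared": n_shared,
                    "count_distance": n_union - n_shared,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "sample_a",
            "sample_b",
            "jaccard_distance",
            "n_union_mutations",
            "n_shared",
            "count_distance",
        ],
    )


@dataclass
class HypermutationConfig:
    """Advisory hypermutation flagging thresholds.

    A sample is flagged when its filtered mutation count exceeds
    ``max(absolute_threshold, fold_threshold * cohort median)``. The
    literature-derived reference burden (background rate x exome size,
    ~30 for a 30 Mb exome at <1/Mb) is reported alongside for context.
    """

    absolute_threshold: float = 300.0
    fold_threshold: float = 10.0
    exome_size_mb: float = 30.0
    background_rate_per_mb: float = 1.0


@dataclass
class HypermutationReport:
    flags: dict[str, bool]
    counts: dict[str, int]
    cohort_median: float
    threshold: float
    reference_count: float

    @property
    def flagged_samples(self) -> list[str]:
        return sorted(s for s, f in self.flags.items() if f)


def flag_hypermutation(
    counts: dict[str, int], cfg: HypermutationConfig | None = None
) -> HypermutationReport:
    """Flag samples whose filtered mutation burden is an outlier.

    Flags are advisory: excluding flagged samples from distance analysis is
    an explicit downstream decision, not done here.
    """
    cfg = cfg or HypermutationConfig()
    if not counts:
        raise ValueError("no counts supplied")
    median = float(np.median(list(counts.values())))
    threshold = max(cfg.absolute_threshold, cfg.fold_threshold * median)
    flags = {s: c > threshold for s, c in counts.items()}
    return HypermutationReport(
        flags=flags,
        counts=dict(counts),
        cohort_median=median,
        threshold=threshold,
        reference_count=cfg.exome_size_mb * cfg.background_rate_per_mb,
    )


# ---------------------------------------------------------------------------
# Mutation sharing structure (presence-pattern partition and tree)
# ---------------------------------------------------------------------------


@dataclass
class SharingTree:
    """Presence-pattern partition of a patient's mutations plus a tree.

    The tree is rooted at "N" (normal tissue, zero mutations); the trunk
    carries the mutations shared by every sample, nested subset patterns
    hang below it, and each sample's leaf branch carries its private
    mutation count. Branch lengths are mutation counts. Patterns that
    overlap without nesting cannot be drawn on a tree; they are attached to
    the deepest compatible ancestor and listed in ``incompatibilities``.
    """

    patient_id: str
    newick: str
    pattern_table: pd.DataFrame  # columns: samples, n_mutations, mean_af
    incompatibilities: list[tuple[frozenset, frozenset]]


class _Node:
    def __init__(self, pattern: frozenset, length: float):
        self.pattern = pattern
        self.length = length
        self.children: list[_Node] = []
        self.leaves: list[tuple[str, float]] = []
        self.depth = 0


def mutation_sharing_tree(m: MutationProfileMatrix) -> SharingTree:
    if not m.mutation_keys:
        raise ValueError("empty mutation matrix")
    samples = list(m.sample_ids)
    all_set = frozenset(samples)
    present = m.af > 0

    counts: dict[frozenset, int] = {}
    afs: dict[frozenset, list[float]] = {}
    for i in range(present.shape[0]):
        pat = frozenset(s for s, p in zip(samples, present[i]) if p)
        if pat:
            counts[pat] = counts.get(pat, 0) + 1
            afs.setdefault(pat, []).extend(m.af[i, present[i]])

    table = pd.DataFrame(
        [
            {
                "samples": ",".join(sorted(pat)),
                "n_mutations": counts[pat],
                "mean_af": float(np.mean(afs[pat])),
            }
            for pat in sorted(counts, key=lambda p: (-len(p), sorted(p)))
        ],
        columns=["samples", "n_mutations", "mean_af"],
    )

    def count(pat: frozenset) -> int:
        return counts.get(pat, 0)

    patterns = counts

    trunk = _Node(all_set, count(all_set))
    placed = [trunk]
    incompat: list[tuple[frozenset, frozenset]] = []

    internal = [
        p
        for p in patterns
        if p != all_set and (len(p) > 1 or len(samples) == 1)
    ]
    if len(samples) == 1:
        internal = []  # single-sample tree is just the trunk branch
    internal.sort(key=lambda p: (-len(p), sorted(p)))
    for pat in internal:
        supersets = [n for n in placed if pat < n.pattern]
        parent = max(supersets, key=lambda n: n.depth)
        for other in placed:
            inter = pat & other.pattern
            if inter and not (pat <= other.pattern or other.pattern <= pat):
                incompat.append((pat, other.pattern))
        node = _Node(pat, count(pat))
        node.depth = parent.depth + 1
        parent.children.append(node)
        placed.append(node)

    for s in samples:
        containing = [n for n in placed if s in n.pattern]
        parent = max(containing, key=lambda n: n.depth)
        private = count(frozenset({s})) if len(samples) > 1 else 0
        parent.leaves.append((s, float(private)))

    def fmt(x: float) -> str:
        return f"{x:g}"

    def render(node: _Node) -> str:
        parts = [f"{name}:{fmt(length)}" for name, length in sorted(node.leaves)]
        parts += [f"{render(c)}:{fmt(c.length)}" for c in node.children]
        return "(" + ",".join(parts) + ")"

    if len(samples) == 1:
        newick = f"({samples[0]}:{fmt(trunk.length)})N;"
    else:
        newick = f"({render(trunk)}:{fmt(trunk.length)})N;"

    if incompat:
        logger.warning(
            "mutation_sharing_tree(%s): %d non-nested overlapping pattern pair(s) "
            "attached to the deepest compatible ancestor",
            m.patient_id,
            len(incompat),
        )
    return SharingTree(m.patient_id, newick, table, incompat)


# ---------------------------------------------------------------------------
# Ingestion
# ---------------------------------------------------------------------------

VARIANT_COLUMNS = [
    "patient_id",
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "region_class",
    "func_class",
    "ref_reads",
    "alt_reads",
    "alt_freq",
]


def read_variant_table(path) -> list[VariantCall]:
    """Read a long-format variant TSV (one row per call per sample)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in VARIANT_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    calls = []
    for _, row in df.iterrows():
        af = row.get("alt_freq")
        calls.append(
            VariantCall(
                patient_id=str(row["patient_id"]),
                sample_id=str(row["sample_id"]),
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                ref=str(row["ref"]),
                alt=str(row["alt"]),
                gene=None if pd.isna(row.get("gene")) else str(row.get("gene")),
                region_class=str(row.get("region_class", "exonic")),
                func_class=str(row.get("func_class", "nonsynonymous SNV")),
                ref_reads=int(row.get("ref_reads", 0)),
                alt_reads=int(row.get("alt_reads", 0)),
                alt_freq=None if af is None or pd.isna(af) else float(af),
            )
        )
    return calls


def write_variant_table(calls: Iterable[VariantCall], path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": c.patient_id,
                "sample_id": c.sample_id,
                "chrom": c.chrom,
                "pos": c.pos,
                "ref": c.ref,
                "alt": c.alt,
                "gene": c.gene or "",
                "region_class": c.region_class,
                "func_class": c.func_class,
                "ref_reads": c.ref_reads,
                "alt_reads": c.alt_reads,
                "alt_freq": c.alt_freq,
            }
            for c in calls
        ],
        columns=VARIANT_COLUMNS,
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_vcf(path, patient_id: str, sample_id: str) -> list[VariantCall]:
    """Read a single-sample VCF annotated with ANNOVAR-style INFO keys.

    Expects ``Func.refGene`` (region class), ``ExonicFunc.refGene``
    (function class, with ANNOVAR underscores mapped to spaces) and
    ``Gene.refGene`` in INFO, and per-allele depths in FORMAT/AD.
    Multi-allelic records must be pre-split (e.g. ``bcftools norm -m-``).
    """
    from cyvcf2 import VCF  # optional dependency

    calls = []
    for var in VCF(str(path)):
        if len(var.ALT) != 1:
            raise ValueError(
                f"{path}: multi-allelic record at {var.CHROM}:{var.POS}; "
                "pre-split with bcftools norm -m-"
            )
        ad = var.format("AD")
        ref_reads, alt_reads = (int(ad[0][0]), int(ad[0][1])) if ad is not None else (0, 0)
        func = var.INFO.get("ExonicFunc.refGene", "nonsynonymous_SNV")
        calls.append(
            VariantCall(
                patient_id=patient_id,
                sample_id=sample_id,
                chrom=var.CHROM,
                pos=var.POS,
                ref=var.REF,
                alt=var.ALT[0],
                gene=var.INFO.get("Gene.refGene"),
                region_class=var.INFO.get("Func.refGene", "exonic"),
                func_class=str(func).replace("_", " "),
                ref_reads=ref_reads,
                alt_reads=alt_reads,
            )
        )
    return calls
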