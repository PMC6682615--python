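"""Methylation beta-value QC, variable-probe selection and the L1 distance.

A beta value is the methylated signal divided by total signal at one CpG
probe, so it lives in [0, 1]. QC drops poor samples first (more than 10%
of probe values missing), then unreliable probes (more than 3 missing
values among the retained samples). Two probe-selection modes follow the
two downstream uses: cohort-level ranking by median absolute deviation
(MAD) feeds clustering/embedding, while the per-patient top-k (default
500) by variance feeds the intra-patient L1 distance

    d = sum_i |P_i - Q_i|,

the total variation between two samples' beta profiles over the selected
probes. Because probes are selected within each patient, L1 distances are
comparable across patients only through the common k.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class BetaMatrix:
    """Probes x samples beta-value matrix plus per-sample metadata.

    ``beta`` is a DataFrame indexed by probe id with sample-id columns;
    missing values are NaN. ``sample_meta`` is indexed by sample id and
    carries at least ``patient_id`` (optional ``idh`` label for stratified
    reporting).
    """

    beta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.beta.index.has_duplicates:
            raise ValueError("duplicate probe ids")
        if self.beta.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        vals = self.beta.to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1] (or be missing)")
        if "patient_id" not in self.sample_meta.columns:
            raise ValueError("sample_meta must carry a patient_id column")
        unknown = set(self.beta.columns) - set(self.sample_meta.index)
        if unknown:
            raise ValueError(f"samples without metadata: {sorted(unknown)}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.beta.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.columns)

    def patient_samples(self, patient_id: str) -> list[str]:
        meta = self.sample_meta.loc[list(self.beta.columns)]
        return [s for s in self.beta.columns if meta.at[s, "patient_id"] == patient_id]

    @property
    def patient_ids(self) -> list[str]:
        meta = self.sample_meta.loc[list(self.beta.columns)]
        return sorted(meta["patient_id"].unique())


def qc_filter(
    m: BetaMatrix,
    max_sample_missing_frac: float = 0.10,
    max_probe_missing: int = 3,
) -> tuple[BetaMatrix, dict]:
    """Drop poor samples, then unreliable probes (strict thresholds).

    Samples with a missing fraction strictly above ``max_sample_missing_frac``
    are dropped first; probes with strictly more than ``max_probe_missing``
    missing values among the remaining samples are dropped second. The
    returned report lists dropped ids with their missing statistics.
    Applying the filter to its own output is a no-op.
    """
    beta = m.beta
    sample_missing = beta.isna().mean(axis=0)
    bad_samples = sample_missing[sample_missing > max_sample_missing_frac]
    kept = beta.drop(columns=bad_samples.index)
    if kept.shape[1] == 0:
        raise ValueError("qc_filter dropped all samples")

    probe_missing = kept.isna().sum(axis=1)
    bad_probes = probe_missing[probe_missing > max_probe_missing]
    kept = kept.drop(index=bad_probes.index)

    report = {
        "dropped_samples": {s: float(f) for s, f in bad_samples.items()},
        "dropped_probes": {p: int(n) for p, n in bad_probes.items()},
        "n_samples_kept": int(kept.shape[1]),
        "n_probes_kept": int(kept.shape[0]),
    }
    logger.info(
        "qc_filter: dropped %d sample(s), %d probe(s)",
        len(bad_samples),
        len(bad_probes),
    )
    out = BetaMatrix(kept, m.sample_meta.loc[list(kept.columns)])
    return out, report


def _complete_probes(beta: pd.DataFrame) -> pd.DataFrame:
    return beta.dropna(axis=0, how="any")


def select_top_mad_probes(m: BetaMatrix, k: int) -> list[str]:
    """The k probes with largest MAD of beta across all samples.

    MAD = median(|beta - median(beta)|), computed over probes with complete
    data (probes with any missing value are removed first). Ties break
    lexicographically by probe id so selection is deterministic.
    """
    complete = _complete_probes(m.beta)
    if k > complete.shape[0]:
        raise ValueError(
            f"k={k} exceeds the {complete.shape[0]} probes with complete data"
        )
    vals = complete.to_numpy(dtype=float)
    mad = np.median(np.abs(vals - np.median(vals, axis=1, keepdims=True)), axis=1)
    order = sorted(zip(-mad, complete.index))
    return [probe for _, probe in order[:k]]


def select_top_variance_probes(
    m: BetaMatrix,
    samples: list[str] | None = None,
    patient_id: str | None = None,
    k: int = 500,
    ddof: int = 1,
) -> list[str]:
    """The k most variable probes within one patient's samples.

    Variance uses the n-1 denominator by default (``ddof``); probes with
    any missing value among the patient's samples are ineligible. With
    fewer than k eligible probes, all are returned with a warning. Ties
    break lexicographically by probe id.
    """
    if samples is None:
        if patient_id is None:
            raise ValueError("supply samples or patient_id")
        samples = m.patient_samples(patient_id)
    if len(samples) < 2:
        raise ValueError("variance selection needs at least 2 samples")
    sub = _complete_probes(m.beta[samples])
    if sub.shape[0] < k:
        warnings.warn(
            f"only {sub.shape[0]} eligible probes (< k={k}); returning all",
            stacklevel=2,
        )
        k = sub.shape[0]
    var = sub.to_numpy(dtype=float).var(axis=1, ddof=ddof)
    order = sorted(zip(-var, sub.index))
    return [probe for _, probe in order[:k]]


def l1_distance(P, Q) -> float:
    """Total-variation (L1) distance between two beta vectors."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"length mismatch: {P.shape} vs {Q.shape}")
    return float(np.abs(P - Q).sum())


def methylation_pair_distances(
    m: BetaMatrix, k: int = 500, ddof: int = 1
) -> pd.DataFrame:
    """L1 distances for every intra-patient sample pair.

    For each patient with >= 2 samples, the top-k most variable probes
    within that patient are selected and the pairwise L1 distance computed
    over them. Patients with a single sample contribute no rows.
    """
    rows = []
    for patient_id in m.patient_ids:
        samples = m.patient_samples(patient_id)
        if len(samples) < 2:
            logger.info("patient %s has <2 samples; no methylation pairs", patient_id)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            probes = select_top_variance_probes(m, samples=samples, k=k, ddof=ddof)
        sub = m.beta.loc[probes, samples]
        for i, a in enumerate(samples):
            for b in samples[i + 1 :]:
                a_id, b_id = sorted((a, b))
                rows.append(
                    {
                        "patient_id": patient_id,
                        "sample_a": a_id,
                        "sample_b": b_id,
                        "l1_distance": l1_distance(sub[a_id], sub[b_id]),
                        "n_probes_used": len(probes),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "sample_a", "sample_b", "l1_distance", "n_probes_used"],
    )


def beta_from_intensities(methylated, unmethylated) -> np.ndarray:
    """beta = M / (M + U) from methylated/unmethylated intensities."""
    M = np.asarray(methylated, dtype=float)
    U = np.asarray(unmethylated, dtype=float)
    total = M + U
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(total > 0, M / np.where(total > 0, total, 1.0), np.nan)
    return beta


def read_beta_matrix(beta_path, meta_path) -> BetaMatrix:
    """Read a probes x samples beta CSV/TSV plus a sample-metadata table.

    The beta table's first column is the probe id; the metadata table maps
    ``sample_id`` to ``patient_id`` (optional ``idh`` column).
    """
    sep = "\t" if str(beta_path).endswith((".tsv", ".txt")) else ","
    beta = pd.read_csv(beta_path, sep=sep, index_col=0)
    beta.index = beta.index.astype(str)
    meta = pd.read_csv(meta_path, sep="\t", dtype=str).set_index("sample_id")
    return BetaMatrix(beta, meta)


def write_beta_matrix(m: BetaMatrix, beta_path, meta_path) -> None:
    m.beta.to_csv(beta_path, float_format="%.4f")
    m.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")
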