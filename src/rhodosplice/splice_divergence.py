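"""Differential intron splicing between condition groups.

Per intron and sample, the data are junction-spanning (spliced) and
intron-retaining read counts.  After coverage/detection filtering, each
condition group is summarised by its read-count-weighted retention
proportion, and the two groups are compared with the square root of the
Jensen-Shannon divergence (base-2 logs, so the statistic lives in [0, 1])
between the two-point retained/spliced distributions.  Significance comes
from a label-randomised, binomially resampled null under the pooled
retention proportion, with Benjamini-Hochberg FDR control; an intron is
called differentially spliced when sqrt-JSD >= ``stat_threshold`` and
q <= ``fdr``.

Differential gene expression is called separately by fold change on
library-size-normalised counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "SplicingCountTable",
    "DifferentialCall",
    "filter_junctions",
    "sqrt_jsd",
    "test_differential",
    "call_de_genes",
]


@dataclass
class SplicingCountTable:
    """Per-intron, per-sample splicing evidence.

    Each frame is introns x samples (identical index/columns):
    ``spliced`` junction-spanning reads, ``retained`` intron-retaining reads,
    ``exon_coverage`` mean flanking-exon depth, ``intron_coverage`` mean
    intron-body depth.  ``conditions`` maps every sample to its group label.
    """

    spliced: pd.DataFrame
    retained: pd.DataFrame
    exon_coverage: pd.DataFrame
    intron_coverage: pd.DataFrame
    conditions: dict[str, str]

    def __post_init__(self) -> None:
        ref = self.spliced
        for name in ("retained", "exon_coverage", "intron_coverage"):
            df = getattr(self, name)
            if not (df.index.equals(ref.index) and df.columns.equals(ref.columns)):
                raise ValueError(f"{name} frame not aligned with spliced frame")
            if (df.to_numpy() < 0).any():
                raise ValueError(f"negative counts in {name}")
        missing = [s for s in ref.columns if s not in self.conditions]
        if missing:
            raise ValueError(f"samples without condition label: {missing}")

    @property
    def samples(self) -> list[str]:
        return list(self.spliced.columns)

    @property
    def intron_ids(self) -> list[str]:
        return list(self.spliced.index)

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s in self.samples:
            out.setdefault(self.conditions[s], []).append(s)
        return out

    def subset(self, intron_ids) -> "SplicingCountTable":
        return replace(
            self,
            spliced=self.spliced.loc[intron_ids],
            retained=self.retained.loc[intron_ids],
            exon_coverage=self.exon_coverage.loc[intron_ids],
            intron_coverage=self.intron_coverage.loc[intron_ids],
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format view for TSV output."""
        frames = []
        for name in ("spliced", "retained", "exon_coverage", "intron_coverage"):
            df = getattr(self, name).stack()
            df.name = name
            frames.append(df)
        out = pd.concat(frames, axis=1).reset_index()
        out.columns = ["intron_id", "sample", *out.columns[2:]]
        out["condition"] = out["sample"].map(self.conditions)
        return out

    @classmethod
    def from_frame(cls, long: pd.DataFrame) -> "SplicingCountTable":
        conditions = dict(zip(long["sample"], long["condition"]))
        frames = {
            name: long.pivot(index="intron_id", columns="sample", values=name)
            for name in ("spliced", "retained", "exon_coverage", "intron_coverage")
        }
        return cls(conditions=conditions, **frames)


@dataclass
class DifferentialCall:
    intron_id: str
    mean_retention: dict[str, float]  # group -> weighted retention proportion
    sqrt_jsd: float
    p_value: float
    q_value: float
    significant: bool


def filter_junctions(table: SplicingCountTable, mean_cov_min: float = 10.0,
                     min_detected_samples: int = 4, exon_cov_min: float = 16.0,
                     intron_cov_min: float = 8.0) -> SplicingCountTable:
    """Coverage/detection filter applied before differential testing.

    An intron is kept iff the mean junction coverage (spliced + retained)
    across samples is strictly > ``mean_cov_min``, splicing is detected
    (>= 1 spliced read) in at least ``min_detected_samples`` samples, and the
    mean flanking-exon and intron-body coverages are >= ``exon_cov_min`` and
    ``intron_cov_min`` respectively.
    """
    total = table.spliced + table.retained
    keep = (
        (total.mean(axis=1) > mean_cov_min)
        & ((table.spliced >= 1).sum(axis=1) >= min_detected_samples)
        & (table.exon_coverage.mean(axis=1) >= exon_cov_min)
        & (table.intron_coverage.mean(axis=1) >= intron_cov_min)
    )
    return table.subset(table.spliced.index[keep])


def sqrt_jsd(p: np.ndarray | list[float], q: np.ndarray | list[float]) -> float:
    """Square root of the Jensen-Shannon divergence (base-2 logs).

    Inputs are two-point distributions (retained fraction, spliced fraction)
    summing to 1; the result is in [0, 1] with 0 iff the distributions are
    equal and 1 at maximal divergence.  ``0 * log 0`` is taken as 0.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if (p < 0).any() or (q < 0).any():
        raise ValueError("distribution components must be non-negative")
    if not (np.isclose(p.sum(), 1.0) and np.isclose(q.sum(), 1.0)):
        raise ValueError("inputs must sum to 1")
    return float(jensenshannon(p, q, base=2))


def _sqrt_jsd_from_props(pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    """Vectorised sqrt-JSD between (pa, 1-pa) and (pb, 1-pb), base-2 logs."""
    pa = np.clip(np.asarray(pa, dtype=float), 0.0, 1.0)
    pb = np.clip(np.asarray(pb, dtype=float), 0.0, 1.0)

    def h(x: np.ndarray) -> np.ndarray:
        # binary entropy in bits, 0*log0 = 0
        with np.errstate(divide="ignore", invalid="ignore"):
            t = -x * np.log2(x) - (1 - x) * np.log2(1 - x)
        return np.where((x <= 0) | (x >= 1), 0.0, t)

    m = 0.5 * (pa + pb)
    jsd = h(m) - 0.5 * (h(pa) + h(pb))
    return np.sqrt(np.clip(jsd, 0.0, 1.0))


def test_differential(table: SplicingCountTable, stat_threshold: float = 0.25,
                      fdr: float = 0.01, n_null: int = 10000,
                      seed: int = 0) -> list[DifferentialCall]:
    """Two-group differential-splicing test per intron.

    Group retention proportions are read-count weighted (summed retained /
    summed total within the group).  The null distribution combines label
    randomisation with binomial resampling of each sample's retained count
    under the pooled retention proportion -- pure permutation alone yields
    only C(4,2)=6 distinct splits at two replicates per condition, too few
    for p-value resolution.  p = (1 + #{null >= observed}) / (1 + n_null);
    q-values are Benjamini-Hochberg.
    """
    groups = table.groups()
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 condition groups, got {sorted(groups)}")
    (ga, samples_a), (gb, samples_b) = sorted(groups.items())
    if min(len(samples_a), len(samples_b)) < 2:
        raise ValueError("need >= 2 samples per condition")

    samples = samples_a + samples_b
    n_a = len(samples_a)
    retained = table.retained[samples].to_numpy(dtype=float)
    total = retained + table.spliced[samples].to_numpy(dtype=float)

    rng = np.random.default_rng(seed)
    n_samples = len(samples)
    # one label randomisation per null replicate, shared across introns
    perms = np.array([rng.permutation(n_samples) for _ in range(n_null)])
    in_a = np.zeros((n_null, n_samples), dtype=bool)
    np.put_along_axis(in_a, perms[:, :n_a], True, axis=1)

    calls: list[DifferentialCall] = []
    skipped: list[str] = []
    stats, pvals, kept_rows = [], [], []
    for i, intron_id in enumerate(table.intron_ids):
        t = total[i]
        r = retained[i]
        ta, tb = t[:n_a].sum(), t[n_a:].sum()
        if ta == 0 or tb == 0:
            skipped.append(intron_id)
            continue
        pa = r[:n_a].sum() / ta
        pb = r[n_a:].sum() / tb
        obs = float(_sqrt_jsd_from_props(np.array([pa]), np.array([pb]))[0])
        pooled = r.sum() / t.sum()
        r_null = rng.binomial(t.astype(int), pooled, size=(n_null, n_samples))
        ra = np.where(in_a, r_null, 0).sum(axis=1)
        rb = r_null.sum(axis=1) - ra
        tta = np.where(in_a, t, 0).sum(axis=1)
        ttb = t.sum() - tta
        with np.errstate(invalid="ignore", divide="ignore"):
            null_stats = _sqrt_jsd_from_props(
                np.where(tta > 0, ra / np.maximum(tta, 1), 0.0),
                np.where(ttb > 0, rb / np.maximum(ttb, 1), 0.0))
        p = (1 + int((null_stats >= obs - 1e-12).sum())) / (1 + n_null)
        stats.append(obs)
        pvals.append(p)
        kept_rows.append((intron_id, {ga: pa, gb: pb}))
    if skipped:
        logger.info("skipped %d introns with a zero-read group: %s",
                    len(skipped), skipped[:10])
    if not kept_rows:
        return []
    qvals = multipletests(pvals, method="fdr_bh")[1]
    for (intron_id, means), stat, p, q in zip(kept_rows, stats, pvals, qvals):
        calls.append(DifferentialCall(
            intron_id=intron_id, mean_retention=means, sqrt_jsd=stat,
            p_value=p, q_value=float(q),
            significant=bool(stat >= stat_threshold and q <= fdr)))
    return calls


def calls_to_frame(calls: list[DifferentialCall]) -> pd.DataFrame:
    if not calls:
        return pd.DataFrame(columns=["intron_id", "sqrt_jsd", "p_value",
                                     "q_value", "significant"])
    groups = sorted(calls[0].mean_retention)
    return pd.DataFrame({
        "intron_id": [c.intron_id for c in calls],
        **{f"retention_{g}": [c.mean_retention[g] for c in calls] for g in groups},
        "sqrt_jsd": [c.sqrt_jsd for c in calls],
        "p_value": [c.p_value for c in calls],
        "q_value": [c.q_value for c in calls],
        "significant": [c.significant for c in calls],
    })


def call_de_genes(counts: pd.DataFrame, conditions: dict[str, str],
                  fold_change_min: float = 2.5) -> pd.DataFrame:
    """Fold-change differential expression on CPM-normalised counts.

    Counts are normalised to counts-per-million per sample; group means are
    compared as max(mean)/max(min(mean), 1) -- the pseudo-count of 1 floors
    the denominator so all-zero groups cannot divide by zero.  A gene is
    called differentially expressed when the fold change is >= 2.5
    (inclusive).  Genes with zero counts in every sample are skipped.
    """
    groups: dict[str, list[str]] = {}
    for s in counts.columns:
        groups.setdefault(conditions[s], []).append(s)
    if len(groups) != 2:
        raise ValueError("need exactly 2 condition groups")
    (ga, sa), (gb, sb) = sorted(groups.items())
    lib = counts.sum(axis=0).astype(float)
    cpm = counts / lib.replace(0, 1) * 1e6
    expressed = counts.sum(axis=1) > 0
    mean_a = cpm.loc[expressed, sa].mean(axis=1)
    mean_b = cpm.loc[expressed, sb].mean(axis=1)
    hi = np.maximum(mean_a, mean_b)
    lo = np.maximum(np.minimum(mean_a, mean_b), 1.0)
    fc = hi / lo
    out = pd.DataFrame({
        "gene_id": mean_a.index,
        f"mean_cpm_{ga}": mean_a.to_numpy(),
        f"mean_cpm_{gb}": mean_b.to_numpy(),
        "fold_change": fc.to_numpy(),
        "direction": np.where(mean_a >= mean_b, f"up_in_{ga}", f"up_in_{gb}"),
        "called": (fc >= fold_change_min).to_numpy(),
    })
    return out.reset_index(drop=True)
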