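"""Restriction-signature methylation calling (DREAM-style).

Sequential digestion with SmaI (blocked by CpG methylation, blunt cut
CCC^GGG) and XmaI (methylation-insensitive, sticky cut C^CCGGG) leaves
distinct prefixes on sequencing reads: reads from a methylated CCCGGG
site begin ``CCGGG``, reads from an unmethylated site begin ``GGG``.
Counting the two signatures per site and sample yields a methylation
fraction at every SmaI site; comparing group mean fractions with a
difference/significance filter yields candidate differential tags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

METHYLATED_SIG = "CCGGG"
UNMETHYLATED_SIG = "GGG"

_VALID_TESTS = ("t_on_fractions", "fisher_on_pooled_counts")


@dataclass
class DreamConfig:
    """Thresholds for methylation calling and differential filtering.

    diff_threshold : group mean difference in percentage points a site
        must exceed (strictly) to pass the filter.
    p_threshold : p-value a site must fall below (strictly).
    min_depth : minimum classified reads (methylated + unmethylated)
        for a (site, sample) fraction to be defined.
    test_kind : "t_on_fractions" (two-sided two-sample Student's t on
        per-sample fractions) or "fisher_on_pooled_counts" (Fisher's
        exact test on group-pooled methylated/unmethylated counts).
    """

    diff_threshold: float = 5.0
    p_threshold: float = 0.1
    min_depth: int = 20
    test_kind: str = "t_on_fractions"

    def validate(self) -> None:
        if self.diff_threshold <= 0 or self.p_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if self.test_kind not in _VALID_TESTS:
            raise ValueError(f"test_kind must be one of {_VALID_TESTS}")


def classify_read(read: str) -> str:
    """Classify a single read as methylated / unmethylated / invalid.

    The caller must normalize to uppercase A/C/G/T/N first; anything
    else raises.
    """
    if not read:
        raise ValueError("empty read")
    if set(read) - set("ACGTN"):
        raise ValueError(f"read contains characters outside ACGTN: {read[:20]!r}")
    if read.startswith(METHYLATED_SIG):
        return "methylated"
    if read.startswith(UNMETHYLATED_SIG):
        return "unmethylated"
    return "invalid"


def _classify_vector(reads: pd.Series) -> pd.Series:
    """Vectorized equivalent of :func:`classify_read` (no validation)."""
    meth = reads.str.startswith(METHYLATED_SIG)
    unmeth = reads.str.startswith(UNMETHYLATED_SIG) & ~meth
    out = pd.Series("invalid", index=reads.index)
    out[meth] = "methylated"
    out[unmeth] = "unmethylated"
    return out


def _resolve_sites(reads: pd.DataFrame, catalog: pd.DataFrame) -> pd.DataFrame:
    """Attach ``site_id`` by provenance or exact 3'-flank lookup."""
    if "site_id" in reads.columns:
        return reads
    if "flank" not in catalog.columns:
        raise ValueError("catalog must carry 'flank' sequences for flank lookup")
    flank_len = int(catalog["flank"].str.len().min())
    lookup = dict(zip(catalog["flank"].str[:flank_len], catalog["site_id"]))
    stripped = reads["read"].str.replace(
        f"^({METHYLATED_SIG}|{UNMETHYLATED_SIG})", "", regex=True
    )
    out = reads.copy()
    out["site_id"] = stripped.str[:flank_len].map(lookup)
    return out


def profile_sites(
    reads: pd.DataFrame,
    catalog: pd.DataFrame,
    config: DreamConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count signatures and compute methylation fractions per site/sample.

    Parameters
    ----------
    reads : DataFrame with columns ``sample_id``, ``read`` and optionally
        ``site_id`` (provenance). Without provenance, reads are resolved
        by exact match of the sequence 3' of the signature against the
        catalog ``flank`` column.
    catalog : site catalog (``site_id``, ``contig``, ``pos`` [, ``flank``]).

    Returns
    -------
    (profiles, qc) : profiles has one row for every catalog site x
        sample with ``n_meth``, ``n_unmeth``, ``n_invalid``, ``fraction``
        (NaN below ``min_depth``) and an ``excluded`` flag; qc reports
        unmapped and invalid read counts per sample — reads resolving to
        no catalog site are counted, never silently dropped.
    """
    config = config or DreamConfig()
    config.validate()
    reads = _resolve_sites(reads, catalog)
    cls = _classify_vector(reads["read"])
    df = reads.assign(_class=cls)
    unmapped = df["site_id"].isna()
    qc = (
        df.assign(unmapped=unmapped)
        .groupby("sample_id", sort=True)
        .agg(
            n_reads=("read", "size"),
            n_unmapped=("unmapped", "sum"),
            n_invalid=("_class", lambda s: int((s == "invalid").sum())),
        )
        .reset_index()
    )
    mapped = df[~unmapped]
    counts = (
        mapped.groupby(["site_id", "sample_id"], sort=True)["_class"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["methylated", "unmethylated", "invalid"], fill_value=0)
        .reset_index()
        .rename(
            columns={
                "methylated": "n_meth",
                "unmethylated": "n_unmeth",
                "invalid": "n_invalid",
            }
        )
    )
    # every catalog site x observed sample appears, even with zero reads
    samples = sorted(df["sample_id"].unique())
    full = pd.MultiIndex.from_product(
        [catalog["site_id"], samples], names=["site_id", "sample_id"]
    ).to_frame(index=False)
    profiles = full.merge(counts, on=["site_id", "sample_id"], how="left").fillna(
        {"n_meth": 0, "n_unmeth": 0, "n_invalid": 0}
    )
    for col in ("n_meth", "n_unmeth", "n_invalid"):
        profiles[col] = profiles[col].astype(int)
    depth = profiles["n_meth"] + profiles["n_unmeth"]
    profiles["fraction"] = np.where(
        depth >= config.min_depth, profiles["n_meth"] / depth.replace(0, np.nan), np.nan
    )
    profiles["excluded"] = depth < config.min_depth
    return profiles, qc


def exclude_repetitive(
    results: pd.DataFrame,
    catalog: pd.DataFrame,
    repeats: list[tuple[str, int, int]],
) -> pd.DataFrame:
    """Drop rows whose cut-site position falls in a repeat interval.

    Intervals are 0-based half-open; an empty repeat list is a no-op.
    ``results`` is any site-keyed DataFrame with a ``site_id`` column.
    """
    if not repeats:
        return results.copy()
    pos = catalog.set_index("site_id")
    masked = set()
    for sid, row in pos.iterrows():
        for contig, start, end in repeats:
            if row["contig"] == contig and start <= row["pos"] < end:
                masked.add(sid)
                break
    return results[~results["site_id"].isin(masked)].copy()


def differential_tags(
    profiles: pd.DataFrame,
    groups: dict[str, str],
    config: DreamConfig | None = None,
    group_order: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Compare per-site methylation between two groups and apply the filter.

    The difference is reported in percentage points (group B minus
    group A, groups in ``group_order`` or sorted label order).
    ``passes_filter`` is ``|difference| > diff_threshold and
    p < p_threshold``. Sites testable in neither configuration (fewer
    than two defined fractions in a group for the t test; no classified
    reads in a group for Fisher) are returned with ``tested = False``.
    """
    config = config or DreamConfig()
    config.validate()
    labels = group_order or tuple(sorted(set(groups.values())))
    if len(set(groups.values())) != 2 or len(labels) != 2:
        raise ValueError("exactly two groups required")
    ga, gb = labels
    df = profiles.copy()
    df["group"] = df["sample_id"].map(groups)
    if df["group"].isna().any():
        missing = sorted(df.loc[df["group"].isna(), "sample_id"].unique())
        raise ValueError(f"samples without group assignment: {missing}")

    rows = []
    for sid, sub in df.groupby("site_id", sort=True):
        a = sub[sub["group"] == ga]
        b = sub[sub["group"] == gb]
        fa = a["fraction"].dropna().to_numpy()
        fb = b["fraction"].dropna().to_numpy()
        mean_a = float(np.mean(fa)) if fa.size else np.nan
        mean_b = float(np.mean(fb)) if fb.size else np.nan
        diff = (mean_b - mean_a) * 100.0
        p = np.nan
        tested = False
        if config.test_kind == "t_on_fractions":
            if fa.size >= 2 and fb.size >= 2:
                tested = True
                if np.var(fa) + np.var(fb) == 0:
                    p = 1.0 if mean_a == mean_b else 0.0
                else:
                    p = float(stats.ttest_ind(fa, fb, equal_var=True).pvalue)
        else:  # fisher_on_pooled_counts
            ka, na = int(a["n_meth"].sum()), int(a["n_unmeth"].sum())
            kb, nb = int(b["n_meth"].sum()), int(b["n_unmeth"].sum())
            if ka + na > 0 and kb + nb > 0:
                tested = True
                p = float(stats.fisher_exact([[ka, na], [kb, nb]]).pvalue)
        passes = bool(
            tested
            and not np.isnan(diff)
            and abs(diff) > config.diff_threshold
            and p < config.p_threshold
        )
        rows.append((sid, mean_a, mean_b, diff, p, tested, passes))
    return pd.DataFrame(
        rows,
        columns=[
            "site_id",
            f"mean_{ga}",
            f"mean_{gb}",
            "difference_pp",
            "p_value",
            "tested",
            "passes_filter",
        ],
    )
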