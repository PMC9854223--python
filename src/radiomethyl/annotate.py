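"""CpG-island detection and promoter-window annotation.

Islands are compositional: a window qualifies when its GC fraction and
its observed/expected CpG ratio — (#CpG x L)/(#C x #G), the classical
Gardiner-Garden & Frommer statistic — both exceed their thresholds
(default 0.6, minimum window 200 bp). Detected islands are the merged
union of all qualifying sliding windows. Differential tags are then
narrowed to those lying inside an island and within +/-1000 bp of a
transcription start site, strand-aware.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CpGIsland:
    contig: str
    start: int
    end: int  # half-open
    gc_fraction: float
    obs_exp_ratio: float

    @property
    def length(self) -> int:
        return self.end - self.start


def gc_fraction(seq: str) -> float:
    """(#G + #C) / (non-N length); N bases excluded from both sides."""
    if not seq:
        raise ValueError("empty sequence")
    n_n = seq.count("N")
    denom = len(seq) - n_n
    if denom == 0:
        raise ValueError("gc_fraction undefined for all-N sequence")
    return (seq.count("G") + seq.count("C")) / denom


def obs_exp_cpg(seq: str) -> float:
    """Observed/expected CpG ratio: (#CpG x L) / (#C x #G).

    CG dinucleotides cannot overlap, so a plain scan counts them.
    """
    n_c, n_g = seq.count("C"), seq.count("G")
    if n_c == 0 or n_g == 0:
        raise ValueError("obs/exp CpG undefined when #C or #G is zero")
    return seq.count("CG") * len(seq) / (n_c * n_g)


def _window_pass(
    seq: str, starts: np.ndarray, width: int, min_gc: float, min_oe: float
) -> np.ndarray:
    """Vectorized threshold test for windows [i, i+width) via prefix sums."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    is_n = arr == ord("N")
    is_cg = np.zeros(len(arr), dtype=bool)
    is_cg[:-1] = is_c[:-1] & is_g[1:]  # CG starting at i

    def cum(x):
        out = np.zeros(len(x) + 1, dtype=np.int64)
        np.cumsum(x, out=out[1:])
        return out

    C, G, N, CG = cum(is_c), cum(is_g), cum(is_n), cum(is_cg)
    e = starts + width
    c = C[e] - C[starts]
    g = G[e] - G[starts]
    n = N[e] - N[starts]
    # CG dinucleotides fully inside the window start at i .. i+width-2
    cg = CG[e - 1] - CG[starts]
    non_n = width - n
    with np.errstate(divide="ignore", invalid="ignore"):
        gc = np.where(non_n > 0, (c + g) / non_n, 0.0)
        oe = np.where(c * g > 0, cg * width / np.where(c * g > 0, c * g, 1), 0.0)
    return (gc > min_gc) & (oe > min_oe) & (non_n > 0)


def detect_islands(
    seq: str,
    min_gc: float = 0.6,
    min_oe: float = 0.6,
    min_length: int = 200,
    window_step: int = 1,
    contig: str = "",
) -> list[CpGIsland]:
    """Merged union of all qualifying ``min_length`` windows.

    Scans window starts at ``window_step`` spacing (1 = exhaustive),
    merges overlapping/adjacent qualifying windows into maximal
    intervals, and reports each interval with its own composition.
    Output is sorted and non-overlapping.
    """
    if len(seq) < min_length:
        raise ValueError("sequence shorter than min_length")
    if window_step < 1:
        raise ValueError("window_step must be >= 1")
    starts = np.arange(0, len(seq) - min_length + 1, window_step)
    ok = _window_pass(seq, starts, min_length, min_gc, min_oe)
    islands: list[CpGIsland] = []
    cur_start = cur_end = None
    for s, good in zip(starts, ok):
        if not good:
            continue
        s, e = int(s), int(s) + min_length
        if cur_end is not None and s <= cur_end:
            cur_end = max(cur_end, e)
        else:
            if cur_end is not None:
                islands.append(_make_island(seq, contig, cur_start, cur_end))
            cur_start, cur_end = s, e
    if cur_end is not None:
        islands.append(_make_island(seq, contig, cur_start, cur_end))
    return islands


def _make_island(seq: str, contig: str, start: int, end: int) -> CpGIsland:
    sub = seq[start:end]
    return CpGIsland(contig, start, end, gc_fraction(sub), obs_exp_cpg(sub))


def promoter_hits(
    sites: pd.DataFrame,
    tss: pd.DataFrame,
    window: int = 1000,
    contigs: set[str] | None = None,
) -> pd.DataFrame:
    """Strand-aware signed distances from cut sites to TSSs.

    One row per same-contig (site, gene) pair; ``distance`` is signed in
    the direction of transcription (negative = upstream of the TSS) and
    ``within_window`` uses the inclusive bound |distance| <= window.

    ``sites`` needs columns ``site_id``, ``contig``, ``pos``; ``tss``
    needs ``gene``, ``contig``, ``pos``, ``strand``. With ``contigs``
    given, an unknown contig in either table raises.
    """
    if contigs is not None:
        for name, tab in (("sites", sites), ("tss", tss)):
            bad = set(tab["contig"]) - set(contigs)
            if bad:
                raise KeyError(f"unknown contig(s) in {name}: {sorted(bad)}")
    merged = sites.merge(tss, on="contig", suffixes=("_site", "_tss"))
    raw = merged["pos_site"] - merged["pos_tss"]
    distance = np.where(merged["strand"] == "+", raw, -raw)
    return pd.DataFrame(
        {
            "site_id": merged["site_id"],
            "gene": merged["gene"],
            "contig": merged["contig"],
            "distance": distance.astype(int),
            "within_window": np.abs(distance) <= window,
        }
    )


def _in_any_island(
    contig: str, pos: int, islands: list[tuple[str, int, int]]
) -> bool:
    return any(c == contig and s <= pos < e for c, s, e in islands)


def select_promoter_tags(
    differential: pd.DataFrame,
    catalog: pd.DataFrame,
    islands: list[tuple[str, int, int]],
    tss: pd.DataFrame,
    window: int = 1000,
    require_island: bool = True,
) -> pd.DataFrame:
    """Narrow passing differential tags to promoter-island tags.

    Keeps tags whose cut-site start lies inside a detected island AND
    within the TSS window (the conjunction; set ``require_island=False``
    for the window-only variant). A site near several TSSs yields one
    row per gene. Output columns: the differential row joined with
    ``gene``, ``distance``, ``in_island``.
    """
    passing = differential[differential["passes_filter"]].copy()
    if passing.empty:
        return passing.assign(gene=pd.Series(dtype=str), distance=pd.Series(dtype=int),
                              in_island=pd.Series(dtype=bool))
    sites = catalog[catalog["site_id"].isin(passing["site_id"])]
    hits = promoter_hits(sites[["site_id", "contig", "pos"]], tss, window=window)
    hits = hits[hits["within_window"]]
    sites = sites.set_index("site_id")
    out = passing.merge(hits[["site_id", "gene", "distance"]], on="site_id", how="inner")
    out["in_island"] = [
        _in_any_island(sites.loc[sid, "contig"], int(sites.loc[sid, "pos"]), islands)
        for sid in out["site_id"]
    ]
    if require_island:
        out = out[out["in_island"]]
    return out.reset_index(drop=True)
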