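"""Self-validation benchmarks: oracle agreement, recovery, model sanity.

Each routine recomputes a pipeline property from scratch on freshly
generated data — brute-force island enumeration, binomial recovery of
planted methylation, detection power at the 5-point/0.1 differential
filter, null-cohort AUC, Wald CI coverage and the importance rank of
the MTNR1B marker under the reference cohort conditions. They power
both the acceptance script and the heavier end of the test suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import annotate, dream, risk_model, simulate

MODEL_EXCLUDED_COLUMNS = (
    "patient_id", "group", "stenosis_extracranial", "stenosis_intracranial",
    "stenosis_total", "nihss_admission", "nihss_discharge",
)


def brute_force_islands(seq: str, min_gc=0.6, min_oe=0.6, w=200):
    """Exhaustive per-window string counting, then merge — the oracle."""
    passing = []
    for i in range(len(seq) - w + 1):
        win = seq[i : i + w]
        non_n = w - win.count("N")
        c, g = win.count("C"), win.count("G")
        if non_n == 0 or c == 0 or g == 0:
            continue
        if (c + g) / non_n > min_gc and win.count("CG") * w / (c * g) > min_oe:
            passing.append((i, i + w))
    merged: list[list[int]] = []
    for s, e in passing:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(m) for m in merged]


def random_island_sequence(gen: np.random.Generator, max_len=2000) -> str:
    """AT-rich background with CpG-rich patches, the island test terrain."""
    parts = []
    for _ in range(gen.integers(2, 6)):
        if gen.random() < 0.5:
            parts.append("".join(gen.choice(list("ACGT"), size=gen.integers(100, 400),
                                            p=[0.3, 0.2, 0.2, 0.3])))
        else:
            n = int(gen.integers(100, 300))
            parts.append("".join(gen.choice(["CG", "C", "G", "A", "T"], size=n,
                                            p=[0.3, 0.2, 0.2, 0.15, 0.15])))
    seq = "".join(parts)[:max_len]
    return seq if len(seq) >= 200 else seq + "A" * (200 - len(seq))


def island_oracle_agreement(n_sequences: int = 100, seed: int = 0) -> float:
    """Fraction of random sequences where detection equals the oracle."""
    gen = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_sequences):
        seq = random_island_sequence(gen)
        got = [(i.start, i.end) for i in annotate.detect_islands(seq)]
        agree += got == brute_force_islands(seq)
    return agree / n_sequences


def dream_recovery_benchmark(
    n_seeds: int = 100,
    n_sites: int = 20,
    n_differential: int = 5,
    n_per_group: int = 8,
    depth: int = 1000,
    fraction_a: float = 0.20,
    fraction_b: float = 0.40,
    seed: int = 0,
) -> dict:
    """Power, false-positive rate and recovery error of the DREAM stage.

    For each seed: plant ``n_differential`` sites with a 20-point group
    difference among ``n_sites``, simulate reads, run the profiling and
    differential filter, and score detection against the plan. Recovery
    error is the mean absolute deviation of estimated from planted
    per-(site, sample) fractions.
    """
    detected = total_diff = false_pos = total_null = 0
    maes = []
    for k in range(n_seeds):
        s = seed + k
        genome = simulate.generate_genome(
            n_contigs=1, contig_length=60_000, n_sites=n_sites, n_islands=2,
            n_tss=4, n_repeats=1, seed=s,
        )
        catalog = genome.site_flanks()
        diff_sites = list(catalog["site_id"][:n_differential])
        truth = simulate.plant_differential_truth(
            genome, n_per_group, diff_sites, fraction_a, fraction_b, seed=s)
        tags = simulate.generate_dream_tags(genome, truth, depth=depth, seed=s)
        profiles, _ = dream.profile_sites(tags, catalog)
        res = dream.differential_tags(profiles, truth.groups)
        passed = set(res.loc[res.passes_filter, "site_id"])
        detected += len(passed & set(diff_sites))
        false_pos += len(passed - set(diff_sites))
        total_diff += n_differential
        total_null += n_sites - n_differential
        merged = profiles.merge(truth.fractions, on=["site_id", "sample_id"],
                                suffixes=("_est", "_true"))
        maes.append(float(np.abs(merged["fraction_est"]
                                 - merged["fraction_true"]).mean()))
    return {
        "power": detected / total_diff,
        "false_positive_rate": false_pos / total_null,
        "recovery_mae": float(np.mean(maes)),
        "n_seeds": n_seeds,
    }


def promoter_narrowing_benchmark(
    n_passing: int = 200, n_qualifying: int = 10
) -> dict:
    """Exact retention of planted island-promoter tags among passing tags."""
    rows, cat, tss, islands = [], [], [], []
    for i in range(n_passing):
        sid = f"t{i:03d}"
        if i < n_qualifying:
            pos = 10_000 + i * 5_000
            islands.append(("c", pos - 50, pos + 150))
            tss.append((f"G{i}", "c", pos + 400, "+"))
        elif i % 3 == 0:  # in an island, no promoter window
            pos = 2_000_000 + i * 5_000
            islands.append(("c", pos - 50, pos + 150))
        elif i % 3 == 1:  # promoter window, no island
            pos = 4_000_000 + i * 5_000
            tss.append((f"H{i}", "c", pos + 300, "-"))
        else:
            pos = 6_000_000 + i * 5_000
        cat.append((sid, "c", pos))
        rows.append((sid, 0.2, 0.4, 20.0, 0.01, True, True))
    differential = pd.DataFrame(
        rows, columns=["site_id", "mean_a", "mean_b", "difference_pp",
                       "p_value", "tested", "passes_filter"])
    out = annotate.select_promoter_tags(
        differential,
        pd.DataFrame(cat, columns=["site_id", "contig", "pos"]),
        islands,
        pd.DataFrame(tss, columns=["gene", "contig", "pos", "strand"]),
    )
    planted = {f"t{i:03d}" for i in range(n_qualifying)}
    return {"retained": len(set(out["site_id"])),
            "exact": set(out["site_id"]) == planted}


def model_candidates(cohort: pd.DataFrame) -> list[str]:
    return [c for c in cohort.columns if c not in MODEL_EXCLUDED_COLUMNS]


def _cohort_cv(spec_fn, seed: int) -> risk_model.CrossValReport:
    cohort = simulate.finalize_cohort(simulate.generate_cohort(spec_fn(seed=seed)))
    labels = (cohort["group"] == "stenosis").astype(int)
    return risk_model.split_and_crossvalidate(
        cohort, labels, model_candidates(cohort), risk_model.SplitPlan(seed=seed))


def null_model_benchmark(n_seeds: int = 20, seed: int = 0) -> dict:
    """Held-out AUC on cohorts with no group differences (expect ~0.5)."""
    aucs = [
        _cohort_cv(simulate.null_cohort_spec, seed + k).performance.auc
        for k in range(n_seeds)
    ]
    return {"mean_auc": float(np.mean(aucs)), "aucs": aucs}


def mtnr1b_rank_benchmark(n_seeds: int = 20, seed: int = 0) -> dict:
    """Importance rank of MTNR1B under the reference cohort conditions."""
    ranks = []
    for k in range(n_seeds):
        imp = _cohort_cv(simulate.reference_cohort_spec, seed + k).importance
        ranks.append(int(imp.index[imp["variable"] == "MTNR1B"][0]) + 1)
    top4 = sum(r <= 4 for r in ranks)
    return {"ranks": ranks, "top4_fraction": top4 / n_seeds}


def wald_coverage_benchmark(
    n_runs: int = 100, n: int = 5000, beta: float = 0.1, seed: int = 0
) -> dict:
    """Coverage of the 95% Wald CI for a planted unit log-odds effect."""
    hits = 0
    for k in range(n_runs):
        gen = np.random.default_rng(seed + k)
        x = gen.normal(0, 4.0, n)
        y = (gen.random(n) < 1 / (1 + np.exp(-beta * x))).astype(int)
        m = risk_model.fit_logistic(pd.DataFrame({"x": x}), y)
        lo, hi = m.params.loc["x", ["ci_low", "ci_high"]]
        hits += lo <= beta <= hi
    return {"coverage": hits / n_runs, "n_runs": n_runs}
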