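"""Synthetic inputs for the methylation-profiling pipeline.

Real inputs to this kind of study — a reference genome with SmaI
(CCCGGG) sites, restriction-signature sequencing reads, and a clinical
validation cohort — are rarely shareable, so every stage here is
exercised on generated data with known ground truth:

* :func:`generate_genome` plants SmaI sites, CpG islands, transcription
  start sites and repeat intervals in a toy genome;
* :func:`generate_dream_tags` emits restriction-signature reads per
  sample with known per-site methylation fractions;
* :func:`generate_cohort` draws patient tables from marginal summary
  statistics (mean +/- SD for labs, prevalence for risk-factor flags),
  optionally with a Gaussian-copula correlation structure;
* :func:`generate_pyro_panel` emulates bisulfite-pyrosequencing results
  across tissue specimen classes with planted above/below-threshold
  genes.

All generators are pure functions of their arguments and a seed; a
single seed is split into per-component child seeds with
``numpy.random.SeedSequence([seed, k])``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

METHYLATED_SIG = "CCGGG"  # sticky-end cut of a methylation-protected site
UNMETHYLATED_SIG = "GGG"  # blunt cut of an unmethylated site
SMAI_SITE = "CCCGGG"

#: canonical specimen classes for the tissue evaluation panel
SPECIMEN_CLASSES = (
    "buffy_coat",
    "endothelial_line",
    "non_plaque_intima",
    "plaque_intima",
    "cea_plaque",
)

#: promoter markers that show >5% methylation across all tissue classes
POSITIVE_GENES = ("EFNA2", "ENOSF1", "GLS2", "KNDC1", "MTNR1B", "PAX8_AS1", "TLDC1")
#: candidate markers whose promoter methylation stays below 5%
NEGATIVE_GENES = ("ACVR1C", "ADCK5", "PACSIN3", "ZNF7")


def _child_rng(seed: int, stream: int) -> np.random.Generator:
    """Deterministic per-component child generator from one master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


# ---------------------------------------------------------------------------
# genome truth
# ---------------------------------------------------------------------------


@dataclass
class GenomeTruth:
    """A toy reference genome plus every planted annotation.

    Coordinates are 0-based; intervals are half-open.
    """

    sequences: dict[str, str]
    sites: list[tuple[str, int]]
    islands: list[tuple[str, int, int]]
    tss: list[tuple[str, str, int, str]]  # (gene, contig, pos, strand)
    repeats: list[tuple[str, int, int]]

    def validate(self) -> None:
        for contig, pos in self.sites:
            seq = self.sequences[contig]
            if seq[pos : pos + 6] != SMAI_SITE:
                raise ValueError(f"site at {contig}:{pos} does not read {SMAI_SITE}")
        for contig, start, end in itertools.chain(self.islands, self.repeats):
            if not (0 <= start < end <= len(self.sequences[contig])):
                raise ValueError(f"interval {contig}:{start}-{end} out of bounds")
        genes = [g for g, *_ in self.tss]
        if len(genes) != len(set(genes)):
            raise ValueError("gene names in TSS annotation are not unique")
        for _, contig, pos, strand in self.tss:
            if strand not in "+-":
                raise ValueError(f"bad strand {strand!r}")
            if not 0 <= pos < len(self.sequences[contig]):
                raise ValueError("TSS out of contig bounds")

    def site_table(self) -> pd.DataFrame:
        """Site catalog: one row per planted SmaI site with a stable id."""
        return pd.DataFrame(
            {
                "site_id": [f"site_{i:04d}" for i in range(len(self.sites))],
                "contig": [c for c, _ in self.sites],
                "pos": [p for _, p in self.sites],
            }
        )

    def site_flanks(self, flank_len: int = 30) -> pd.DataFrame:
        """Site catalog plus the genomic sequence 3' of each cut."""
        tab = self.site_table()
        flanks = [
            self.sequences[c][p + 6 : p + 6 + flank_len] for c, p in self.sites
        ]
        return tab.assign(flank=flanks)

    def tss_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.tss, columns=["gene", "contig", "pos", "strand"])


#: AT-rich bulk-genome base frequencies (GC ~ 0.40)
_BACKGROUND_P = (0.30, 0.20, 0.20, 0.30)


def _background(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length, p=_BACKGROUND_P))


def _island_block(rng: np.random.Generator, length: int) -> str:
    # CG-dinucleotide-rich composition: comfortably above GC 0.6 and
    # observed/expected 0.6 in every window
    parts: list[str] = []
    n = 0
    while n < length:
        r = rng.random()
        if r < 0.45:
            parts.append("CG")
            n += 2
        elif r < 0.80:
            parts.append(rng.choice(["C", "G"]))
            n += 1
        else:
            parts.append(rng.choice(["A", "T"]))
            n += 1
    return "".join(parts)[:length]


def generate_genome(
    n_contigs: int = 1,
    contig_length: int = 50_000,
    n_sites: int = 20,
    n_islands: int = 2,
    n_tss: int = 5,
    n_repeats: int = 1,
    seed: int = 0,
    island_length: int = 400,
    repeat_length: int = 500,
) -> GenomeTruth:
    """Generate a toy genome with planted SmaI sites and annotations.

    Half of the TSSs (rounded up) are placed within 1000 bp of a planted
    site so promoter annotation has positive cases; the rest are kept
    more than 2000 bp from every site. One site is embedded at the
    centre of each island while sites remain, so island-promoter tags
    exist by construction.
    """
    rng = _child_rng(seed, 0)
    if min(n_contigs, contig_length) < 1 or min(n_sites, n_islands, n_tss, n_repeats) < 0:
        raise ValueError("counts must be non-negative and lengths positive")

    # distribute features across contigs round-robin
    contig_names = [f"contig_{i}" for i in range(n_contigs)]
    per_contig: dict[str, dict[str, int]] = {c: {"islands": 0, "repeats": 0, "sites": 0} for c in contig_names}
    for i in range(n_islands):
        per_contig[contig_names[i % n_contigs]]["islands"] += 1
    for i in range(n_repeats):
        per_contig[contig_names[i % n_contigs]]["repeats"] += 1
    sites_in_islands = min(n_islands, n_sites)
    standalone = n_sites - sites_in_islands
    for i in range(standalone):
        per_contig[contig_names[i % n_contigs]]["sites"] += 1

    sequences: dict[str, str] = {}
    sites: list[tuple[str, int]] = []
    islands: list[tuple[str, int, int]] = []
    repeats: list[tuple[str, int, int]] = []
    island_site_slots: list[tuple[str, int]] = []  # islands still owed a site

    for contig in contig_names:
        counts = per_contig[contig]
        blocks: list[tuple[str, int]] = (
            [("island", island_length)] * counts["islands"]
            + [("repeat", repeat_length)] * counts["repeats"]
            + [("site", 6)] * counts["sites"]
        )
        order = rng.permutation(len(blocks))
        blocks = [blocks[i] for i in order]
        used = sum(length for _, length in blocks)
        n_gaps = len(blocks) + 1
        free = contig_length - used
        if free < n_gaps * 20:
            raise ValueError(
                f"infeasible packing: {len(blocks)} features need more than "
                f"{contig_length} bp on {contig}"
            )
        gap_sizes = 20 + rng.multinomial(free - n_gaps * 20, np.full(n_gaps, 1 / n_gaps))

        pieces: list[str] = []
        cursor = 0
        for (kind, length), gap in zip(blocks, gap_sizes):
            pieces.append(_background(rng, gap))
            cursor += gap
            if kind == "island":
                block = _island_block(rng, island_length)
                mid = island_length // 2
                block = block[:mid] + SMAI_SITE + block[mid + 6 :]
                islands.append((contig, cursor, cursor + island_length))
                island_site_slots.append((contig, cursor + mid))
                pieces.append(block)
            elif kind == "repeat":
                # low-complexity tandem repeat, LINE/Alu stand-in
                unit = _background(rng, 8)
                block = (unit * (repeat_length // 8 + 1))[:repeat_length]
                repeats.append((contig, cursor, cursor + repeat_length))
                pieces.append(block)
            else:
                sites.append((contig, cursor))
                pieces.append(SMAI_SITE)
            cursor += length
        pieces.append(_background(rng, gap_sizes[-1]))
        sequences[contig] = "".join(pieces)[:contig_length].ljust(contig_length, "A")

    # islands owed a site: take the first n needed (all have one embedded)
    sites = island_site_slots[:sites_in_islands] + sites
    sites.sort()

    # TSS placement: positives near sites, negatives far from all sites
    tss: list[tuple[str, str, int, str]] = []
    n_near = (n_tss + 1) // 2 if sites else 0
    site_pool = list(sites)
    for g in range(n_near):
        contig, pos = site_pool[g % len(site_pool)]
        offset = int(rng.integers(-900, 901))
        tpos = int(np.clip(pos + offset, 0, contig_length - 1))
        tss.append((f"GENE_{g:03d}", contig, tpos, rng.choice(["+", "-"])))
    # negatives: sample exactly from the complement of site neighbourhoods,
    # preferring a 2 kb margin but falling back to just outside the 1 kb
    # promoter window when the contig is densely packed
    def _free_positions(contig: str, margin: int) -> list[tuple[int, int]]:
        blocked = sorted(
            (max(0, p - margin), min(contig_length, p + margin + 1))
            for c, p in sites if c == contig
        )
        free, cursor = [], 0
        for s, e in blocked:
            if s > cursor:
                free.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < contig_length:
            free.append((cursor, contig_length))
        return free

    for g in range(n_near, n_tss):
        contig = contig_names[int(rng.integers(n_contigs))]
        free = _free_positions(contig, 2000) or _free_positions(contig, 1001)
        if not free:
            raise ValueError("infeasible packing: cannot place TSS away from sites")
        total = sum(e - s for s, e in free)
        offset = int(rng.integers(total))
        for s, e in free:
            if offset < e - s:
                tpos = s + offset
                break
            offset -= e - s
        tss.append((f"GENE_{g:03d}", contig, tpos, rng.choice(["+", "-"])))

    genome = GenomeTruth(sequences, sites, islands, tss, repeats)
    genome.validate()
    return genome


# ---------------------------------------------------------------------------
# methylation truth and restriction-signature tags
# ---------------------------------------------------------------------------


@dataclass
class TruthMethylation:
    """Planted per-(site, sample) methylation fractions and group labels."""

    fractions: pd.DataFrame  # columns: site_id, sample_id, fraction
    groups: dict[str, str]  # sample_id -> group label

    def validate(self, genome: GenomeTruth | None = None) -> None:
        f = self.fractions["fraction"]
        if ((f < 0) | (f > 1)).any():
            raise ValueError("methylation fractions must lie in [0, 1]")
        unknown = set(self.fractions["sample_id"]) - set(self.groups)
        if unknown:
            raise ValueError(f"samples without group assignment: {sorted(unknown)}")
        if genome is not None:
            valid = set(genome.site_table()["site_id"])
            bad = set(self.fractions["site_id"]) - valid
            if bad:
                raise ValueError(f"unknown site ids in truth: {sorted(bad)}")


def plant_differential_truth(
    genome: GenomeTruth,
    n_per_group: int = 8,
    differential_sites: list[str] | None = None,
    fraction_a: float = 0.20,
    fraction_b: float = 0.40,
    seed: int = 0,
    groups: tuple[str, str] = ("no_stenosis", "stenosis"),
) -> TruthMethylation:
    """Truth table with a planted group difference at selected sites.

    Null sites get a common per-site fraction drawn uniformly on
    [0.05, 0.95], identical in both groups; differential sites get
    ``fraction_a`` in the first group and ``fraction_b`` in the second.
    """
    rng = _child_rng(seed, 1)
    site_ids = list(genome.site_table()["site_id"])
    differential = set(differential_sites or [])
    unknown = differential - set(site_ids)
    if unknown:
        raise ValueError(f"unknown differential site ids: {sorted(unknown)}")
    samples = {
        f"{g}_{i:02d}": g for g in groups for i in range(n_per_group)
    }
    rows = []
    for sid in site_ids:
        null_frac = float(rng.uniform(0.05, 0.95))
        for sample, group in samples.items():
            if sid in differential:
                frac = fraction_a if group == groups[0] else fraction_b
            else:
                frac = null_frac
            rows.append((sid, sample, frac))
    truth = TruthMethylation(
        pd.DataFrame(rows, columns=["site_id", "sample_id", "fraction"]), samples
    )
    truth.validate(genome)
    return truth


def generate_dream_tags(
    genome: GenomeTruth,
    truth: TruthMethylation,
    depth: int = 100,
    error_rate: float = 0.0,
    seed: int = 0,
    flank_len: int = 30,
) -> pd.DataFrame:
    """Emit restriction-signature reads for every (site, sample) pair.

    Each read is the cut signature (``CCGGG`` for a methylation-protected
    site cut by the methylation-insensitive enzyme, ``GGG`` for a blunt
    cut of an unmethylated site) followed by the genomic sequence 3' of
    the hexamer. ``error_rate`` flips a read's signature symmetrically.

    Returns a DataFrame with columns ``sample_id``, ``site_id``,
    ``read`` containing exactly ``depth * n_sites * n_samples`` rows.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must lie in [0, 0.5)")
    truth.validate(genome)
    rng = _child_rng(seed, 2)
    flanks = genome.site_flanks(flank_len).set_index("site_id")["flank"]

    sample_col, site_col, read_col = [], [], []
    tab = truth.fractions.sort_values(["site_id", "sample_id"], kind="stable")
    for sid, sample, frac in tab.itertuples(index=False):
        p_eff = frac * (1 - error_rate) + (1 - frac) * error_rate
        meth = rng.random(depth) < p_eff
        flank = flanks[sid]
        reads = np.where(meth, METHYLATED_SIG + flank, UNMETHYLATED_SIG + flank)
        sample_col.append(np.full(depth, sample, dtype=object))
        site_col.append(np.full(depth, sid, dtype=object))
        read_col.append(reads)
    return pd.DataFrame(
        {
            "sample_id": np.concatenate(sample_col),
            "site_id": np.concatenate(site_col),
            "read": np.concatenate(read_col),
        }
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


@dataclass
class ContinuousVar:
    """Marginal description of a continuous variable, per group.

    ``dist`` selects the marginal family: "normal" (draw clipped at
    ``lower`` after sampling) or "lognormal" (moment-matched to the
    given mean and SD, for right-skewed positive labs such as CRP,
    lipoprotein (a) or triglycerides, whose normal emulation would put
    group tails on disjoint support).
    """

    name: str
    by_group: dict[str, tuple[float, float]]  # group -> (mean, sd)
    lower: float | None = 0.0  # truncation bound applied after sampling
    dist: str = "normal"

    def validate(self) -> None:
        for g, (mean, sd) in self.by_group.items():
            if sd < 0:
                raise ValueError(f"{self.name}: SD must be >= 0 in group {g}")
            if self.dist == "lognormal" and mean <= 0:
                raise ValueError(f"{self.name}: lognormal needs mean > 0 (group {g})")
        if self.dist not in ("normal", "lognormal"):
            raise ValueError(f"{self.name}: unknown dist {self.dist!r}")


@dataclass
class BinaryVar:
    """Marginal description of a yes/no variable, per group."""

    name: str
    by_group: dict[str, float]  # group -> prevalence of "yes"

    def validate(self) -> None:
        for g, p in self.by_group.items():
            if not 0 <= p <= 1:
                raise ValueError(f"{self.name}: prevalence must lie in [0,1] (group {g})")


@dataclass
class CohortSpec:
    """Recipe for a synthetic patient cohort.

    ``correlation``, if given, is ``(names, matrix)``: a Gaussian-copula
    correlation over the named variables (continuous and/or binary);
    all other variables are sampled independently.
    """

    groups: dict[str, int]
    continuous: list[ContinuousVar]
    binary: list[BinaryVar]
    correlation: tuple[list[str], np.ndarray] | None = None
    seed: int = 0

    def validate(self) -> None:
        if any(n < 1 for n in self.groups.values()):
            raise ValueError("group sizes must be >= 1")
        for v in self.continuous:
            v.validate()
        for v in self.binary:
            v.validate()
        names = [v.name for v in self.continuous] + [v.name for v in self.binary]
        if len(names) != len(set(names)):
            raise ValueError("duplicate variable names in cohort spec")
        if self.correlation is not None:
            cnames, R = self.correlation
            R = np.asarray(R, dtype=float)
            if R.shape != (len(cnames), len(cnames)):
                raise ValueError("correlation matrix shape does not match names")
            if not np.allclose(R, R.T):
                raise ValueError(f"correlation matrix is not symmetric:\n{R}")
            if not np.allclose(np.diag(R), 1.0):
                raise ValueError(f"correlation matrix diagonal is not 1:\n{R}")
            if np.linalg.eigvalsh(R).min() < -1e-8:
                raise ValueError(
                    f"correlation matrix is not positive semidefinite:\n{R}"
                )
            unknown = set(cnames) - set(names)
            if unknown:
                raise ValueError(f"correlation names not in spec: {sorted(unknown)}")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one record per patient from a :class:`CohortSpec`.

    Continuous variables are normal draws clipped at ``lower``
    (truncation applied after sampling); binary variables are Bernoulli
    at the group prevalence, encoded "yes"/"no". Correlated variables
    share a multivariate-normal latent vector; a binary variable maps
    its latent quantile below the prevalence threshold to "yes", so the
    marginal prevalence is preserved.
    """
    spec.validate()
    rng = _child_rng(spec.seed, 3)
    cont = {v.name: v for v in spec.continuous}
    binv = {v.name: v for v in spec.binary}
    corr_names: list[str] = spec.correlation[0] if spec.correlation else []
    if spec.correlation:
        R = np.asarray(spec.correlation[1], dtype=float)
        w, V = np.linalg.eigh(R)
        L = V @ np.diag(np.sqrt(np.clip(w, 0, None)))
    frames = []
    pid = 0
    for group, n in spec.groups.items():
        cols: dict[str, object] = {}
        if corr_names:
            z = rng.standard_normal((n, len(corr_names))) @ L.T
            zmap = {name: z[:, j] for j, name in enumerate(corr_names)}
        else:
            zmap = {}
        for name, v in cont.items():
            mean, sd = v.by_group[group]
            latent = zmap.get(name)
            if latent is None:
                latent = rng.standard_normal(n)
            if v.dist == "lognormal" and sd > 0:
                # moment-matched: sigma^2 = ln(1 + cv^2), mu = ln(mean) - sigma^2/2
                sigma2 = np.log1p((sd / mean) ** 2)
                x = np.exp(np.log(mean) - sigma2 / 2 + np.sqrt(sigma2) * latent)
            else:
                x = mean + sd * latent
            if v.lower is not None:
                x = np.maximum(x, v.lower)
            cols[name] = x
        for name, v in binv.items():
            prev = v.by_group[group]
            latent = zmap.get(name)
            if latent is None:
                u = rng.random(n)
            else:
                u = norm.cdf(latent)
            cols[name] = np.where(u < prev, "yes", "no")
        frame = pd.DataFrame(cols)
        frame.insert(0, "patient_id", [f"P{pid + i:04d}" for i in range(n)])
        frame.insert(1, "group", group)
        pid += n
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def reference_cohort_spec(seed: int = 0) -> CohortSpec:
    """Default spec: an ischemic-stroke validation cohort.

    50 patients without and 334 with cranial-vessel stenosis, with the
    marginal summaries (mean +/- SD, prevalences) of the emulated
    validation cohort: demographics, stroke severity, vessel stenosis
    counts, clinical risk-factor flags, fasting labs and seven
    gene-promoter methylation percentages. A Gaussian-copula correlation
    encodes standard clinical clusters (lipid panel, glycemic panel
    including diabetes status, the two stroke-severity scores,
    age-creatinine-hypertension, WBC-CRP); all other variables,
    including the methylation markers, are independent.
    """
    A, B = "no_stenosis", "stenosis"

    def c(name, ma, sa, mb, sb, lower=0.0):
        return ContinuousVar(name, {A: (ma, sa), B: (mb, sb)}, lower)

    continuous = [
        c("age", 63.8, 8.8, 69.4, 8.9),
        c("bmi", 25.0, 3.0, 24.9, 3.2),
        c("nihss_admission", 0.5, 1.4, 0.9, 1.9),
        c("nihss_discharge", 0.2, 0.6, 0.4, 1.0),
        c("stenosis_extracranial", 0.0, 0.0, 2.1, 1.2),
        c("stenosis_intracranial", 0.0, 0.0, 2.4, 2.5),
        c("hemoglobin", 13.7, 1.4, 13.7, 1.6),
        c("wbc", 6456.6, 1512.9, 7027.3, 2105.0),
        c("platelets", 234.5, 46.5, 222.3, 62.2),
        ContinuousVar("hs_crp", {A: (1.6, 2.2), B: (3.8, 9.9)}, dist="lognormal"),
        c("homocysteine", 8.7, 2.4, 10.0, 4.7),
        c("creatinine", 0.7, 0.2, 0.8, 0.2),
        c("total_cholesterol", 181.9, 34.2, 169.9, 42.2),
        ContinuousVar("triglyceride", {A: (130.9, 73.9), B: (126.8, 80.4)}, dist="lognormal"),
        c("hdl_cholesterol", 51.7, 13.7, 45.9, 11.3),
        c("ldl_cholesterol", 108.8, 27.2, 102.6, 35.7),
        c("apolipoprotein_a", 134.3, 27.1, 122.8, 25.1),
        c("apolipoprotein_b", 89.4, 20.3, 88.4, 25.0),
        ContinuousVar("lipoprotein_a", {A: (15.2, 11.5), B: (25.2, 21.7)}, dist="lognormal"),
        c("hba1c", 5.9, 0.8, 6.3, 1.4),
        c("fasting_glucose", 113.3, 29.8, 129.5, 56.2),
        c("EFNA2", 10.0, 2.4, 10.4, 4.1),
        c("ENOSF1", 48.1, 17.7, 49.6, 17.0),
        c("GLS2", 35.6, 6.7, 35.3, 6.9),
        c("KNDC1", 21.4, 4.4, 22.3, 5.2),
        c("MTNR1B", 25.4, 8.7, 22.7, 6.7),
        c("PAX8_AS1", 63.6, 16.9, 58.9, 19.7),
        c("TLDC1", 18.3, 6.1, 18.3, 5.8),
    ]
    binary = [
        BinaryVar("male", {A: 0.52, B: 0.65}),
        BinaryVar("hypertension", {A: 0.34, B: 0.64}),
        BinaryVar("diabetes", {A: 0.14, B: 0.32}),
        BinaryVar("smoking", {A: 0.24, B: 0.32}),
    ]

    markers = ["EFNA2", "ENOSF1", "GLS2", "KNDC1", "MTNR1B", "PAX8_AS1", "TLDC1"]
    corr_names = [
        "total_cholesterol", "ldl_cholesterol", "hdl_cholesterol", "triglyceride",
        "apolipoprotein_a", "apolipoprotein_b",
        "diabetes", "hba1c", "fasting_glucose",
        "age", "creatinine", "hypertension",
        "nihss_admission", "nihss_discharge",
        "wbc", "hs_crp", "male", "smoking",
    ] + markers
    R = np.eye(len(corr_names))
    blocks = {
        ("total_cholesterol", "ldl_cholesterol"): 0.90,
        ("total_cholesterol", "hdl_cholesterol"): 0.20,
        ("total_cholesterol", "triglyceride"): 0.30,
        ("total_cholesterol", "apolipoprotein_a"): 0.15,
        ("total_cholesterol", "apolipoprotein_b"): 0.75,
        ("ldl_cholesterol", "hdl_cholesterol"): 0.05,
        ("ldl_cholesterol", "triglyceride"): 0.20,
        ("ldl_cholesterol", "apolipoprotein_a"): 0.05,
        ("ldl_cholesterol", "apolipoprotein_b"): 0.85,
        ("hdl_cholesterol", "triglyceride"): -0.35,
        ("hdl_cholesterol", "apolipoprotein_a"): 0.80,
        ("hdl_cholesterol", "apolipoprotein_b"): -0.05,
        ("triglyceride", "apolipoprotein_a"): -0.20,
        ("triglyceride", "apolipoprotein_b"): 0.30,
        ("apolipoprotein_a", "apolipoprotein_b"): 0.05,
        ("diabetes", "hba1c"): 0.55,
        ("diabetes", "fasting_glucose"): 0.45,
        ("hba1c", "fasting_glucose"): 0.60,
        ("diabetes", "age"): 0.20,
        ("diabetes", "hypertension"): 0.25,
        ("age", "creatinine"): 0.30,
        ("age", "hypertension"): 0.25,
        ("creatinine", "hypertension"): 0.15,
        ("nihss_admission", "nihss_discharge"): 0.70,
        ("wbc", "hs_crp"): 0.35,
        ("male", "smoking"): 0.30,
    }
    # age-related methylation drift: promoter methylation of the marker
    # genes rises with age, while the stenosis label lowers MTNR1B — the
    # suppression structure that makes age-adjusted hypomethylation a
    # stronger predictor than the raw group difference
    for g in markers:
        blocks[("age", g)] = 0.30
    for i, gi in enumerate(markers):
        for gj in markers[i + 1 :]:
            blocks[(gi, gj)] = 0.15  # shared drift among markers
    idx = {n: i for i, n in enumerate(corr_names)}
    for (x, y), r in blocks.items():
        R[idx[x], idx[y]] = R[idx[y], idx[x]] = r

    return CohortSpec(
        groups={A: 50, B: 334},
        continuous=continuous,
        binary=binary,
        correlation=(corr_names, R),
        seed=seed,
    )


def null_cohort_spec(seed: int = 0) -> CohortSpec:
    """Reference cohort spec with all group differences removed.

    Both groups share the no-stenosis marginals (group sizes kept), so
    any downstream predictive signal is spurious — the negative control
    for the risk model.
    """
    spec = reference_cohort_spec(seed=seed)
    for v in spec.continuous:
        v.by_group = {g: v.by_group["no_stenosis"] for g in spec.groups}
    for v in spec.binary:
        v.by_group = {g: v.by_group["no_stenosis"] for g in spec.groups}
    return spec


def finalize_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Derive the combined stenosis count column from its two components."""
    out = cohort.copy()
    out["stenosis_total"] = (
        out["stenosis_extracranial"] + out["stenosis_intracranial"]
    )
    return out


# ---------------------------------------------------------------------------
# tissue panel / pyrosequencing emulation
# ---------------------------------------------------------------------------


def generate_pyro_panel(
    positive_genes: tuple[str, ...] = POSITIVE_GENES,
    negative_genes: tuple[str, ...] = NEGATIVE_GENES,
    classes: tuple[str, ...] = SPECIMEN_CLASSES,
    n_specimens: int = 10,
    n_cpgs: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-specimen pyrosequencing-style methylation values.

    Positive genes get class baselines drawn on (8, 65)% so every
    specimen-class mean exceeds 5%; negative genes draw on (0.5, 4)%.
    Returns a long DataFrame with one row per (gene, class, specimen)
    and per-CpG percentages in ``cpg_values`` (semicolon-joined) plus
    their mean in ``gene_mean``.
    """
    rng = _child_rng(seed, 4)
    rows = []
    for gene in positive_genes + negative_genes:
        positive = gene in positive_genes
        for cls in classes:
            base = rng.uniform(8, 65) if positive else rng.uniform(0.5, 4)
            for s in range(n_specimens):
                cpgs = np.clip(base + rng.normal(0, 1.0, size=n_cpgs), 0, 100)
                rows.append(
                    (
                        gene,
                        cls,
                        f"{cls}_{s:02d}",
                        ";".join(f"{v:.3f}" for v in cpgs),
                        float(np.mean(cpgs)),
                    )
                )
    return pd.DataFrame(
        rows, columns=["gene", "specimen_class", "specimen_id", "cpg_values", "gene_mean"]
    )


def panel_table(pyro: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-specimen results to the gene x specimen-class mean table."""
    return (
        pyro.pivot_table(index="gene", columns="specimen_class", values="gene_mean")
        .rename_axis(columns=None)
    )
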