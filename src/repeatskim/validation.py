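"""End-to-end validation scenarios against simulator ground truth.

Each function builds a defined study condition with the bundled simulator,
runs the full estimation path (similarity search, clustering, annotation,
contig layout, junction counting, statistics) and returns the measured
quantities next to their known true values.  The scenarios dimension the
published study down to desk scale: three diploid species of ~10 Mbp
instead of 23 species of 1.8-13.4 Gbp, with read coverages chosen so that
every estimator sees the same per-repeat read depths that drive its
behaviour at full scale.  The test suite and the acceptance script both
run these functions; all randomness derives from the single ``seed``
argument.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Sequence

import numpy as np
import pandas as pd

from repeatskim.align import exhaustive_hits, find_similarity_hits
from repeatskim.conserve import hs_ho
from repeatskim.iolayer import SpeciesProfile, TaggedRead, bundled_species_table, reads_for_coverage
from repeatskim.quantify import (
    abundance_from_proportion,
    abundance_table,
    aggregate_by_class,
    annotate_clusters,
    compare_replicates,
    replicate_summary,
)
from repeatskim.readcluster import build_clusters, build_contigs
from repeatskim.simgenome import (
    SimFamilySpec,
    build_species_genome,
    library_tiles,
    make_ancestral_library,
    sample_reads,
)
from repeatskim.sizestats import pairwise_contribution
from repeatskim.sololtr import estimate_rsf_for_cluster


def _sub_seed(seed: int, k: int) -> int:
    return (seed * 1009 + k) % (2**31 - 1)


# ---------------------------------------------------------------------------
# published-panel arithmetic

def panel_arithmetic() -> dict[str, float]:
    """Quantities derivable from the bundled 23-species panel alone:
    genome-size ratios, the comparative 0.01x read pool, sequencing
    coverage, and the % <-> Mbp abundance conversions of the flagship
    satellite and Ogre figures."""
    df = bundled_species_table()
    profiles = {
        str(r["code"]): SpeciesProfile(str(r["code"]), int(r["1C_bp"]), int(r["ploidy"]))
        for _, r in df.iterrows()
    }
    cx = {c: p.genome_size_1Cx for c, p in profiles.items()}
    pool = sum(reads_for_coverage(cx[c], 0.01, 100) for c in cx)
    run_reads = dict(zip(df["code"], df["run_reads"]))

    def mbp(code: str, percent: float) -> float:
        rec = abundance_from_proportion(percent / 100, profiles[code])
        return rec.mbp_per_1Cx(profiles[code])

    return {
        "genome_size_fold_range": max(cx.values()) / min(cx.values()),
        "comparative_pool_reads_million": pool / 1e6,
        "vsa_sequencing_coverage": run_reads["VSA"] * 100 / cx["VSA"],
        "vfb_satellite_mbp": mbp("VFB", 6.97),
        "las_satellite_mbp": mbp("LAS", 10.7),
        "vvl_satellite_mbp": mbp("VVL", 12.3),
        "vsa_satellite_mbp": mbp("VSA", 10.4),
        "vfb_ogre_gbp": mbp("VFB", 54.0) / 1e3,
        "ver_vsl_size_ratio": max(cx["VER"], cx["VSL"]) / min(cx["VER"], cx["VSL"]),
    }


# ---------------------------------------------------------------------------
# clustering abundance recovery (three species, ~10 Mbp, 0.05x)

def _three_species_specs(codes: Sequence[str]) -> list[SimFamilySpec]:
    return [
        SimFamilySpec("ogre1", "ltr_retrotransposon", 3000, {c: 100 for c in codes},
                      ltr_length=300, divergence_per_species=0.02,
                      repeat_class="LTR/Ty3-gypsy/Ogre"),
        SimFamilySpec("satA", "satellite", 33, {c: 6000 for c in codes},
                      divergence_per_species=0.02, repeat_class="satellite"),
        SimFamilySpec("disp1", "dispersed_other", 1500, {c: 100 for c in codes},
                      divergence_per_species=0.02, repeat_class="dispersed"),
    ]


def _clustering_recovery_once(seed: int, coverage: float,
                              genome_size: int) -> pd.DataFrame:
    codes = ["AAA", "BBB", "CCC"]
    specs = _three_species_specs(codes)
    library = make_ancestral_library(specs, _sub_seed(seed, 1))
    reads: list[TaggedRead] = []
    truths = {}
    for c in codes:
        profile = SpeciesProfile(c, genome_size)
        genome, truth = build_species_genome(library, profile, specs, _sub_seed(seed, 1))
        truths[c] = truth
        reads += sample_reads(genome, profile, coverage, seed=_sub_seed(seed, 2))
    hits = find_similarity_hits(reads)
    clusters, _singles = build_clusters(hits, reads)
    clusters = [c for c in clusters if c.size >= 5]
    clusters = annotate_clusters(clusters, reads, library_tiles(library))
    n_by = defaultdict(int)
    for r in reads:
        n_by[r.species_code] += 1
    est = defaultdict(float)
    for cl in clusters:
        if cl.annotation in truths[codes[0]].families:
            for c, n in cl.per_species_counts.items():
                est[(c, cl.annotation)] += n / n_by[c]
    rows = []
    for c in codes:
        for fam in truths[c].families:
            truth_p = truths[c].proportion(fam)
            est_p = est[(c, fam)]
            rows.append({
                "species_code": c, "family_id": fam,
                "true_proportion": truth_p, "estimated_proportion": est_p,
                "relative_error": (est_p - truth_p) / truth_p,
            })
    return pd.DataFrame(rows)


def clustering_recovery(seed: int, coverage: float = 0.05,
                        genome_size: int = 10_000_000,
                        n_seeds: int = 5) -> pd.DataFrame:
    """Pooled comparative clustering of 3 simulated species; per family and
    species, the cluster-based genome proportion against simulator truth.

    The relative error is averaged over ``n_seeds`` independent simulations
    so the recovery bound is a bound on the estimator, not on one sampling
    draw."""
    runs = [
        _clustering_recovery_once(_sub_seed(seed, 200 + i), coverage, genome_size)
        for i in range(n_seeds)
    ]
    stacked = pd.concat(runs, ignore_index=True)
    out = (
        stacked.groupby(["species_code", "family_id"], as_index=False)
        .agg(
            true_proportion=("true_proportion", "mean"),
            estimated_proportion=("estimated_proportion", "mean"),
            relative_error=("relative_error", "mean"),
            worst_single_run_error=("relative_error", lambda s: s.abs().max()),
        )
    )
    out["n_seeds"] = n_seeds
    return out


# ---------------------------------------------------------------------------
# seeded search vs the exhaustive oracle

def oracle_agreement(seed: int, n_family: int = 170, n_tandem: int = 50,
                     n_background: int = 80) -> dict[str, float]:
    """Hit-set agreement between the seeded search and the no-seeding
    exhaustive aligner on 300 mixed reads (family reads near the 90%
    identity boundary, tandem-repeat reads, random background)."""
    rng = np.random.default_rng(_sub_seed(seed, 3))

    def rand(n):
        return "".join("ACGT"[i] for i in rng.integers(0, 4, n))

    def mutated(s, m):
        out = list(s)
        for p in rng.choice(len(s), size=m, replace=False):
            out[p] = "ACGT"[("ACGT".index(out[p]) + int(rng.integers(1, 4))) % 4]
        return "".join(out)

    comp = str.maketrans("ACGT", "TGCA")
    reads = []
    template = rand(320)
    for i in range(n_family):
        s = int(rng.integers(0, 221))
        seq = mutated(template[s : s + 100], int(rng.integers(0, 12)))
        if rng.random() < 0.5:
            seq = seq.translate(comp)[::-1]
        reads.append(TaggedRead("F", f"F_{i:04d}", seq))
    monomer = rand(33)
    arr = monomer * 9
    for i in range(n_tandem):
        s = int(rng.integers(0, len(arr) - 100))
        reads.append(TaggedRead("S", f"S_{i:04d}", mutated(arr[s : s + 100], int(rng.integers(0, 4)))))
    for i in range(n_background):
        reads.append(TaggedRead("B", f"B_{i:04d}", rand(100)))

    def key(h):
        return (h.read_a, h.read_b, h.orientation, h.identity, h.hit_length,
                h.span_a, h.span_b)

    seeded = {key(h) for h in find_similarity_hits(reads)}
    brute = {key(h) for h in exhaustive_hits(reads)}
    union = len(seeded | brute)
    agree = len(seeded & brute)
    return {
        "n_reads": len(reads),
        "n_hits_seeded": len(seeded),
        "n_hits_exhaustive": len(brute),
        "jaccard": agree / union if union else 1.0,
        "identical": seeded == brute,
    }


# ---------------------------------------------------------------------------
# Rsf parameter recovery

def rsf_single_run(solo_to_full: float, seed: int, copies: int = 6000,
                   genome_size: int = 12_000_000, unit_length: int = 1200,
                   ltr_length: int = 250, detect_coverage: float = 0.015,
                   count_coverage: float = 0.2) -> dict[str, float]:
    """One genome at a target solo:full ratio; junction model from cluster
    contigs at skim coverage, Rsf counted on the deeper read set."""
    code = "SIM"
    solo_fraction = solo_to_full / (1 + solo_to_full) if solo_to_full else 0.0
    spec = SimFamilySpec(
        "fam", "ltr_retrotransposon", unit_length, {code: copies},
        ltr_length=ltr_length, solo_fraction={code: solo_fraction},
        divergence_per_species=0.02,
    )
    library = make_ancestral_library([spec], seed)
    profile = SpeciesProfile(code, genome_size)
    genome, truth = build_species_genome(library, profile, [spec], seed)
    ft = truth.families["fam"]
    detect_reads = sample_reads(genome, profile, detect_coverage, seed=_sub_seed(seed, 4))
    hits = find_similarity_hits(detect_reads)
    clusters, _ = build_clusters(hits, detect_reads)
    contigs = build_contigs(clusters[0], detect_reads, hits)
    count_reads = sample_reads(genome, profile, count_coverage, seed=_sub_seed(seed, 5))
    result, _models, _rej = estimate_rsf_for_cluster(contigs, count_reads, code,
                                                     element_label="fam")
    return {
        "target": solo_to_full,
        "true_ratio": ft.solo_count / ft.full_count if ft.full_count else float("nan"),
        "estimate": result.rsf if result is not None else float("nan"),
        "LU": result.LU if result is not None else 0,
        "Lx": result.Lx if result is not None else 0,
    }


def rsf_recovery(seed: int, ratios: Sequence[float] = (0.0, 0.5, 1.0, 2.0),
                 n_seeds: int = 5) -> pd.DataFrame:
    """Mean estimated Rsf over ``n_seeds`` independent genomes per target
    solo:full ratio."""
    rows = []
    for r in ratios:
        runs = [rsf_single_run(r, _sub_seed(seed, 100 + 17 * int(r * 10) + i))
                for i in range(n_seeds)]
        est = np.array([x["estimate"] for x in runs], dtype=float)
        tru = np.array([x["true_ratio"] for x in runs], dtype=float)
        rows.append({
            "target_ratio": r,
            "mean_true": float(np.mean(tru)),
            "mean_estimate": float(np.nanmean(est)),
            "n_detected": int(np.sum(~np.isnan(est))),
            "n_runs": n_seeds,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hs/Ho conservation patterns

def hsho_patterns(seed: int, coverage: float = 0.03,
                  genome_size: int = 10_000_000) -> dict[str, float]:
    """Three species sharing a conserved low-divergence element family and
    four largely species-private satellite families; Hs/Ho medians per
    group and two-component evidence of bimodality for the pooled mixture."""
    from sklearn.mixture import GaussianMixture

    codes = ["AAA", "BBB", "CCC"]
    specs = [
        SimFamilySpec("angela", "ltr_retrotransposon", 3000, {c: 200 for c in codes},
                      ltr_length=300, divergence_per_species=0.01,
                      lineage_divergence=0.01, repeat_class="LTR/Ty1-copia/Angela"),
    ]
    for i in range(4):
        specs.append(
            SimFamilySpec(f"sat{i}", "satellite", 160, {c: 1500 for c in codes},
                          divergence_per_species=0.01, lineage_divergence=0.09,
                          satellite_array_size=300, repeat_class="satellite", seed=i)
        )
    library = make_ancestral_library(specs, _sub_seed(seed, 6))
    reads: list[TaggedRead] = []
    for c in codes:
        profile = SpeciesProfile(c, genome_size)
        genome, _ = build_species_genome(library, profile, specs, _sub_seed(seed, 6))
        reads += sample_reads(genome, profile, coverage, seed=_sub_seed(seed, 7))
    hits = find_similarity_hits(reads)
    clusters, _ = build_clusters(hits, reads)
    clusters = annotate_clusters([c for c in clusters if c.size > 20], reads,
                                 library_tiles(library))
    by_id = {r.read_id: r for r in reads}
    groups: dict[str, list[TaggedRead]] = {"conserved": [], "satellite": []}
    for cl in clusters:
        if cl.annotation == "angela":
            groups["conserved"].extend(by_id[x] for x in sorted(cl.member_reads))
        elif cl.annotation and cl.annotation.startswith("sat"):
            groups["satellite"].extend(by_id[x] for x in sorted(cl.member_reads))
    groups["mixture"] = groups["conserved"] + groups["satellite"]
    records, hists = hs_ho(groups)

    def med(label):
        vals = [r.log10_ratio for r in records
                if r.repeat_group == label and r.log10_ratio is not None]
        return float(np.median(vals)) if vals else float("nan")

    vals = np.array([r.log10_ratio for r in records
                     if r.repeat_group == "mixture" and r.log10_ratio is not None])
    vals = vals.reshape(-1, 1)
    bic1 = GaussianMixture(1, random_state=0).fit(vals).bic(vals)
    bic2 = GaussianMixture(2, random_state=0).fit(vals).bic(vals)
    return {
        "conserved_median_log_ratio": med("conserved"),
        "satellite_median_log_ratio": med("satellite"),
        "satellite_zero_ho_fraction":
            hists["satellite"].n_zero_ho / hists["satellite"].n_records,
        "mixture_bic_one_component": float(bic1),
        "mixture_bic_two_components": float(bic2),
        "mixture_bimodal": bool(bic2 < bic1),
    }


# ---------------------------------------------------------------------------
# replicate library variation

def replicate_variation(seed: int, coverage: float = 0.05,
                        genome_size: int = 10_000_000) -> dict[str, float]:
    """Two independent read samplings of one genome: per-cluster
    fold-variation of satellite vs mobile-element clusters, and the effect
    of class-level aggregation."""
    code = "SIM"
    specs = []
    mobile = [("ogre", "LTR/Ty3-gypsy/Ogre"), ("chromo", "LTR/Ty3-gypsy/Chromovirus"),
              ("maximus", "LTR/Ty1-copia/Maximus")]
    for i, (fam, cls) in enumerate(mobile):
        specs.append(SimFamilySpec(fam, "ltr_retrotransposon", 3000, {code: 100},
                                   ltr_length=300, divergence_per_species=0.02,
                                   repeat_class=cls, seed=i))
    for i in range(6):
        specs.append(SimFamilySpec(f"sat{i}", "satellite", 160, {code: 250},
                                   divergence_per_species=0.01, satellite_array_size=60,
                                   repeat_class="satellite", seed=100 + i))
    library = make_ancestral_library(specs, _sub_seed(seed, 8))
    profile = SpeciesProfile(code, genome_size)
    genome, _ = build_species_genome(library, profile, specs, _sub_seed(seed, 8))
    tiles = library_tiles(library)
    label_map = {s.family_id: f"{s.repeat_class}/{s.family_id}" for s in specs}

    def one(sub):
        reads = sample_reads(genome, profile, coverage, seed=sub)
        hits = find_similarity_hits(reads)
        clusters, _ = build_clusters(hits, reads)
        clusters = annotate_clusters([c for c in clusters if c.size >= 5], reads,
                                     tiles, label_map=label_map)
        return abundance_table(clusters, {code: profile}, {code: len(reads)},
                               include_remainder=False)

    r1 = one(_sub_seed(seed, 9))
    r2 = one(_sub_seed(seed, 10))
    per_cluster = compare_replicates(r1, r2, group_level=1)
    per_cluster = per_cluster[per_cluster["repeat_class"] != "unclassified"]
    summ = replicate_summary(per_cluster).set_index("group")
    class_cmp = compare_replicates(aggregate_by_class(r1, 1), aggregate_by_class(r2, 1))
    class_cmp = class_cmp.set_index("repeat_class")
    return {
        "satellite_mean_cluster_fold": float(summ.loc["satellite", "mean_fold"]),
        "mobile_mean_cluster_fold": float(summ.loc["LTR", "mean_fold"]),
        "satellite_class_fold": float(class_cmp.loc["satellite", "fold"]),
        "mobile_class_fold": float(class_cmp.loc["LTR", "fold"]),
    }


# ---------------------------------------------------------------------------
# genome-size contribution recovery

def contribution_recovery(seed: int, driver_fraction: float = 0.60,
                          n_species: int = 12) -> dict[str, float]:
    """Synthetic abundance panel in which one repeat class explains a known
    fraction of every pairwise genome-size difference; the pairwise
    contribution statistic should recover that fraction, and the class
    contributions plus residual must close to 100%."""
    rng = np.random.default_rng(_sub_seed(seed, 11))
    sizes = np.sort(rng.uniform(1.8e9, 13.4e9, n_species))
    profiles = {f"S{i:02d}": SpeciesProfile(f"S{i:02d}", int(g))
                for i, g in enumerate(sizes)}
    rows = []
    for code, p in profiles.items():
        g = p.genome_size_1Cx / 1e6
        rows += [
            {"species_code": code, "repeat_class": "driver",
             "mbp_per_1Cx": driver_fraction * g + rng.normal(0, 5)},
            {"species_code": code, "repeat_class": "secondary",
             "mbp_per_1Cx": 0.2 * g + rng.normal(0, 5)},
            {"species_code": code, "repeat_class": "flat",
             "mbp_per_1Cx": 40 + rng.normal(0, 2)},
        ]
    ab = pd.DataFrame(rows)
    per_class = pairwise_contribution(ab, profiles).set_index("repeat_class")
    all_df = (ab.groupby("species_code", as_index=False)["mbp_per_1Cx"].sum()
              .assign(repeat_class="all_repeats"))
    all_contrib = pairwise_contribution(all_df, profiles).loc[0, "avg_contribution_pct"]
    return {
        "driver_true_pct": 100 * driver_fraction,
        "driver_recovered_pct": float(per_class.loc["driver", "avg_contribution_pct"]),
        "class_sum_pct": float(per_class["avg_contribution_pct"].sum()),
        "all_repeats_pct": float(all_contrib),
    }
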