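"""Repeat abundance versus genome size.

Two derived statistics per repeat class over a species panel: (i) ordinary
least-squares regression of absolute abundance (Mbp/1Cx) on monoploid
genome size, reported as R^2 with the F-test p-value; (ii) the average
contribution to pairwise genome-size differences, the mean over species
pairs (oriented so the larger genome comes first) of
100 x (A_i - A_j) / (G_i - G_j) with abundance and genome size in the same
units.  Contributions are additive: summed over classes (plus the
non-repeat residual) they account for 100% of each pairwise difference.
A negative contribution means the class is, on average, more abundant in
the smaller genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from repeatskim.iolayer import SpeciesProfile


@dataclass(frozen=True)
class ContributionRecord:
    repeat_class: str
    r_squared: float | None
    p_value: float | None
    abundance_min: float
    abundance_max: float
    avg_contribution_pct: float | None
    n_species: int
    n_pairs_used: int = 0
    n_pairs_degenerate: int = 0


def _abundance_matrix(
    abundance_table: pd.DataFrame, species_profiles: Mapping[str, SpeciesProfile]
) -> tuple[pd.DataFrame, np.ndarray]:
    """Wide (species x class) Mbp/1Cx matrix plus matching 1Cx sizes (Mbp)."""
    required = {"species_code", "repeat_class", "mbp_per_1Cx"}
    if not required.issubset(abundance_table.columns):
        raise ValueError(f"abundance table must have columns {sorted(required)}")
    wide = abundance_table.pivot_table(
        index="species_code", columns="repeat_class", values="mbp_per_1Cx", aggfunc="sum"
    )
    wide = wide.loc[[c for c in wide.index if c in species_profiles]]
    sizes = np.array([species_profiles[c].genome_size_1Cx / 1e6 for c in wide.index])
    return wide, sizes


def correlate_with_genome_size(
    abundance_table: pd.DataFrame,
    species_profiles: Mapping[str, SpeciesProfile],
) -> pd.DataFrame:
    """Per-class OLS of Mbp/1Cx on genome size (Gbp/1Cx): R^2 and p.

    Classes observed in fewer than 3 species are reported with NaN and
    flagged ``defined = False``.  p-values are raw (no multiple-testing
    correction).
    """
    wide, sizes_mbp = _abundance_matrix(abundance_table, species_profiles)
    sizes_gbp = sizes_mbp / 1e3
    rows = []
    for rclass in wide.columns:
        y = wide[rclass]
        mask = y.notna().to_numpy()
        n = int(mask.sum())
        if n < 3:
            rows.append(
                {"repeat_class": rclass, "r_squared": np.nan, "p_value": np.nan,
                 "n_species": n, "defined": False}
            )
            continue
        x = sizes_gbp[mask]
        yy = y.to_numpy()[mask]
        if np.allclose(yy, yy[0]) or np.allclose(x, x[0]):
            # constant abundance (or degenerate sizes): no variance explained
            rows.append(
                {"repeat_class": rclass, "r_squared": 0.0, "p_value": 1.0,
                 "n_species": n, "defined": True}
            )
            continue
        fit = stats.linregress(x, yy)
        rows.append(
            {
                "repeat_class": rclass,
                "r_squared": float(fit.rvalue**2),
                "p_value": float(fit.pvalue),
                "n_species": n,
                "defined": True,
            }
        )
    return pd.DataFrame(rows)


def pairwise_contribution(
    abundance_table: pd.DataFrame,
    species_profiles: Mapping[str, SpeciesProfile],
    weighted: bool = False,
) -> pd.DataFrame:
    """Average contribution of each class to pairwise genome-size differences.

    For each unordered species pair oriented so G_i > G_j:
    c = 100 x (A_i - A_j) / (G_i - G_j), A and G both in Mbp.  The default
    is the unweighted mean over pairs; ``weighted=True`` weights each pair
    by its size difference.  Pairs with equal genome sizes are excluded and
    counted.
    """
    wide, sizes = _abundance_matrix(abundance_table, species_profiles)
    n = len(wide.index)
    if n < 2:
        raise ValueError("need at least 2 species with abundances and genome sizes")
    rows = []
    for rclass in wide.columns:
        a = wide[rclass].fillna(0.0).to_numpy()
        contribs, wts = [], []
        degenerate = 0
        for i, j in combinations(range(n), 2):
            gi, gj, ai, aj = sizes[i], sizes[j], a[i], a[j]
            if gi < gj:
                gi, gj, ai, aj = gj, gi, aj, ai
            if gi == gj:
                degenerate += 1
                continue
            contribs.append(100.0 * (ai - aj) / (gi - gj))
            wts.append(gi - gj)
        if contribs:
            value = float(
                np.average(contribs, weights=wts if weighted else None)
            )
        else:
            value = np.nan
        rows.append(
            {
                "repeat_class": rclass,
                "avg_contribution_pct": value,
                "n_pairs_used": len(contribs),
                "n_pairs_degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def contribution_table(
    abundance_table: pd.DataFrame,
    species_profiles: Mapping[str, SpeciesProfile],
    weighted: bool = False,
) -> list[ContributionRecord]:
    """One record per repeat class: R^2, p, abundance range, avg contribution."""
    corr = correlate_with_genome_size(abundance_table, species_profiles).set_index("repeat_class")
    contr = pairwise_contribution(abundance_table, species_profiles, weighted).set_index("repeat_class")
    wide, _ = _abundance_matrix(abundance_table, species_profiles)
    records = []
    for rclass in wide.columns:
        y = wide[rclass].dropna()
        r2 = corr.loc[rclass, "r_squared"]
        p = corr.loc[rclass, "p_value"]
        records.append(
            ContributionRecord(
                repeat_class=rclass,
                r_squared=None if np.isnan(r2) else float(r2),
                p_value=None if np.isnan(p) else float(p),
                abundance_min=float(y.min()),
                abundance_max=float(y.max()),
                avg_contribution_pct=float(contr.loc[rclass, "avg_contribution_pct"]),
                n_species=int(corr.loc[rclass, "n_species"]),
                n_pairs_used=int(contr.loc[rclass, "n_pairs_used"]),
                n_pairs_degenerate=int(contr.loc[rclass, "n_pairs_degenerate"]),
            )
        )
    return records
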