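"""Survey-level aggregation of resolved introns.

The survey table has one row per intron with the columns

    genome_id, phylum, intron_id, intron_class, category, site,
    amino_acid, anticodon, length, subgroup, has_heg

and the operations here compute the headline survey quantities: per-phylum
retention rates, per-genome copy-number statistics, the insertion-position
matrix for tRNA-hosted introns, the intron length distribution with the
>500 bp HEG-eligibility flag, and structural subgroup assignment from
subgroup covariance-model scores.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SURVEY_COLUMNS = [
    "genome_id", "phylum", "intron_id", "intron_class", "category", "site",
    "amino_acid", "anticodon", "length", "subgroup", "has_heg",
]

SUBGROUPS = ("IA", "IB", "IC", "ID", "IE")
HEG_LENGTH_THRESHOLD = 500
DEFAULT_MIN_GENOMES = 20


def empty_survey() -> pd.DataFrame:
    return pd.DataFrame(columns=SURVEY_COLUMNS)


def validate_survey(survey: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SURVEY_COLUMNS if c not in survey.columns]
    if missing:
        raise ValueError(f"survey table missing columns: {missing}")
    if len(survey) and (survey["length"] <= 0).any():
        raise ValueError("survey contains non-positive intron lengths")
    return survey


def assign_subgroup(intron_id: str, subgroup_score_table: pd.DataFrame) -> str:
    """Best-scoring subgroup model for one intron.

    The score table holds (intron_id, model, score) rows, one per subgroup
    covariance model scanned. Ties break lexicographically by model name
    (logged); no rows at all yields "unassigned".
    """
    rows = subgroup_score_table[subgroup_score_table["intron_id"] == intron_id]
    if rows.empty:
        return "unassigned"
    top_score = rows["score"].max()
    top = sorted(rows.loc[rows["score"] == top_score, "model"])
    if len(top) > 1:
        logger.info("intron %s: subgroup score tie among %s, keeping %s",
                    intron_id, top, top[0])
    return top[0]


def retention_rate(survey: pd.DataFrame, genome_phylum_map: Mapping[str, str],
                   min_genomes: int = DEFAULT_MIN_GENOMES) -> pd.DataFrame:
    """Per-phylum, per-intron-class retention rates.

    Rate = genomes with at least one intron of the class / all genomes of the
    phylum in the input set. Phyla under *min_genomes* stay in the full table
    with ``in_plot`` False. Survey genomes missing from the map are a hard
    error.
    """
    validate_survey(survey)
    unmapped = sorted(set(survey["genome_id"]) - set(genome_phylum_map))
    if unmapped:
        raise ValueError(f"genomes missing from the phylum map: {unmapped}")
    phyla = pd.Series(dict(genome_phylum_map), name="phylum")
    totals = phyla.value_counts()
    classes = sorted(survey["intron_class"].unique()) or ["groupI"]
    rows = []
    for phylum, total in totals.sort_index().items():
        genomes_of = {g for g, p in genome_phylum_map.items() if p == phylum}
        for cls in classes:
            with_introns = set(
                survey.loc[survey["intron_class"] == cls, "genome_id"]
            ) & genomes_of
            rows.append({
                "phylum": phylum, "intron_class": cls, "n_genomes": int(total),
                "n_with_introns": len(with_introns),
                "rate": len(with_introns) / total,
                "in_plot": total >= min_genomes,
            })
    return pd.DataFrame(rows)


def copy_number_stats(survey: pd.DataFrame) -> pd.DataFrame:
    """Mean/sd/median intron copies per genome, per intron class.

    Computed over genomes carrying at least one intron of that class; the
    standard deviation is the sample sd (n-1), reported as 0 with a
    ``degenerate`` flag when only one genome qualifies.
    """
    validate_survey(survey)
    if survey.empty:
        return pd.DataFrame(columns=["intron_class", "n_genomes", "mean", "sd",
                                     "median", "degenerate"])
    rows = []
    for cls, sub in survey.groupby("intron_class"):
        copies = sub.groupby("genome_id").size().to_numpy()
        degenerate = len(copies) < 2
        rows.append({
            "intron_class": cls, "n_genomes": len(copies),
            "mean": float(np.mean(copies)),
            "sd": 0.0 if degenerate else float(np.std(copies, ddof=1)),
            "median": float(np.median(copies)),
            "degenerate": degenerate,
        })
    return pd.DataFrame(rows)


def position_matrix(survey: pd.DataFrame) -> pd.DataFrame:
    """Counts of tRNA-hosted introns keyed by (phylum, site, amino_acid).

    Marginals conserve the total tRNA-hosted intron count.
    """
    validate_survey(survey)
    trna = survey[survey["category"] == "tRNA"]
    if trna.empty:
        return pd.DataFrame(columns=["phylum", "site", "amino_acid", "count"])
    out = (trna.groupby(["phylum", "site", "amino_acid"]).size()
           .reset_index(name="count"))
    return out.sort_values(["phylum", "site", "amino_acid"]).reset_index(drop=True)


def length_histogram(survey: pd.DataFrame, bins: Sequence[int] | int = 20
                     ) -> tuple[pd.DataFrame, dict]:
    """Intron length histogram plus HEG-eligibility flags (>500 bp)."""
    validate_survey(survey)
    lengths = survey["length"].to_numpy(dtype=float)
    if lengths.size == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "count"]), {
            "n": 0, "min": None, "max": None, "n_over_500": 0}
    counts, edges = np.histogram(lengths, bins=bins)
    hist = pd.DataFrame({
        "bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})
    flags = {
        "n": int(lengths.size),
        "min": int(lengths.min()), "max": int(lengths.max()),
        "mean": float(lengths.mean()),
        "n_over_500": int((lengths > HEG_LENGTH_THRESHOLD).sum()),
    }
    return hist, flags


def category_proportions(survey: pd.DataFrame) -> pd.DataFrame:
    """Proportion of introns per host category (sums to 1)."""
    validate_survey(survey)
    if survey.empty:
        return pd.DataFrame(columns=["category", "count", "proportion"])
    counts = survey.groupby("category").size().reset_index(name="count")
    counts["proportion"] = counts["count"] / counts["count"].sum()
    return counts


def subgroup_proportions(survey: pd.DataFrame) -> pd.DataFrame:
    """Proportion of introns per structural subgroup (sums to 1)."""
    validate_survey(survey)
    if survey.empty:
        return pd.DataFrame(columns=["subgroup", "count", "proportion"])
    counts = survey.groupby("subgroup").size().reset_index(name="count")
    counts["proportion"] = counts["count"] / counts["count"].sum()
    return counts


def write_stats_tables(survey: pd.DataFrame, genome_phylum_map: Mapping[str, str],
                       out_dir: str | Path,
                       min_genomes: int = DEFAULT_MIN_GENOMES) -> dict[str, Path]:
    """Write the per-panel TSVs and return their paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    tables = {
        "stats_retention.tsv": retention_rate(survey, genome_phylum_map, min_genomes),
        "stats_positions.tsv": position_matrix(survey),
        "stats_lengths.tsv": length_histogram(survey)[0],
        "stats_subgroups.tsv": subgroup_proportions(survey),
        "stats_copy_number.tsv": copy_number_stats(survey),
        "stats_categories.tsv": category_proportions(survey),
    }
    for name, table in tables.items():
        path = out_dir / name
        table.to_csv(path, sep="\t", index=False)
        paths[name] = path
    return paths
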