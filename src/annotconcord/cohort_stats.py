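"""Descriptive statistics over per-species tables (tRNA complement,
proteome sizes).

The quartile convention is fixed to linear interpolation between order
statistics (numpy's default); the median of an even-sized sample is the mean
of the two middle values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .model import AnnotationSet, TRNARecord

__all__ = [
    "median_iqr",
    "TrnaSummary",
    "trna_summary",
    "proteome_summary",
    "SEC_ISOTYPES",
    "SUPPRESSOR_ISOTYPES",
]

# tRNAscan-SE isotype labels for selenocysteine and suppressor tRNAs
SEC_ISOTYPES = {"SeC", "SeC(e)", "SelCys"}
SUPPRESSOR_ISOTYPES = {"Sup", "Supres"}


def median_iqr(values: Sequence[float]) -> Tuple[float, float, float]:
    """(median, Q1, Q3) with linear-interpolation quantiles."""
    if len(values) == 0:
        raise ValueError("median_iqr of an empty sequence")
    arr = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(arr, [25.0, 50.0, 75.0], method="linear")
    return float(med), float(q1), float(q3)


@dataclass
class TrnaSummary:
    per_species: pd.DataFrame  # indexed by species
    cohort: pd.DataFrame  # rows: median, q1, q3 of each numeric column
    sec_species_fraction: float
    suppressor_species_fraction: float


def _species_trna_row(
    records: List[TRNARecord], genome_bp: Union[int, None]
) -> Dict[str, float]:
    confirmed = [r for r in records if not r.is_pseudo]
    n_total = len(records)
    n_confirmed = len(confirmed)
    n_pseudo = n_total - n_confirmed
    row: Dict[str, float] = {
        "total_count": n_total,
        "confirmed_count": n_confirmed,
        "pseudo_count": n_pseudo,
        "pseudo_pct": 100.0 * n_pseudo / n_total if n_total else 0.0,
        "intron_pct": (
            100.0 * sum(1 for r in confirmed if r.intron_count > 0) / n_confirmed
            if n_confirmed
            else 0.0
        ),
        "has_sec": float(any(r.isotype in SEC_ISOTYPES for r in records)),
        "has_suppressor": float(
            any(r.isotype in SUPPRESSOR_ISOTYPES for r in records)
        ),
    }
    if genome_bp is not None:
        row["genome_bp"] = genome_bp
        row["density_per_mbp"] = n_confirmed / (genome_bp / 1e6) if genome_bp else 0.0
        # occupancy counts every predicted row, pseudogenes included
        row["occupancy_pct"] = (
            100.0 * sum(r.span_bp for r in records) / genome_bp if genome_bp else 0.0
        )
    isotype_counts: Dict[str, int] = {}
    for r in confirmed:
        isotype_counts[r.isotype] = isotype_counts.get(r.isotype, 0) + 1
    for isotype, count in isotype_counts.items():
        row[f"share_{isotype}_pct"] = 100.0 * count / n_confirmed
    return row


def trna_summary(
    records_by_species: Mapping[str, List[TRNARecord]],
    genome_bp: Union[Mapping[str, int], None] = None,
) -> TrnaSummary:
    """Per-species tRNA metrics and cohort medians/IQRs.

    Per species: total/confirmed/pseudogene counts, pseudogene percentage,
    intron-bearing percentage among confirmed tRNAs, isotype shares among
    confirmed tRNAs, presence flags for selenocysteine and suppressor
    isotypes; plus density per Mbp and genomic occupancy when genome sizes
    are supplied. Occupancy sums |end - begin| + 1 over all rows (reverse-
    strand rows contribute positively), pseudogenes included.
    """
    if not records_by_species:
        raise ValueError("no species supplied")
    rows = {}
    for species in sorted(records_by_species):
        size = None
        if genome_bp is not None:
            if species not in genome_bp:
                raise ValueError(f"no genome size for species {species!r}")
            size = genome_bp[species]
        rows[species] = _species_trna_row(records_by_species[species], size)
    per_species = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    per_species.index.name = "species"

    cohort_rows = {}
    for col in per_species.columns:
        med, q1, q3 = median_iqr(per_species[col].tolist())
        cohort_rows[col] = {"median": med, "q1": q1, "q3": q3}
    cohort = pd.DataFrame.from_dict(cohort_rows, orient="index")[
        ["median", "q1", "q3"]
    ]
    return TrnaSummary(
        per_species=per_species,
        cohort=cohort,
        sec_species_fraction=float(per_species["has_sec"].mean()),
        suppressor_species_fraction=float(per_species["has_suppressor"].mean()),
    )


def proteome_summary(
    species_data: Mapping[str, Union[Sequence[int], AnnotationSet]],
) -> Tuple[pd.DataFrame, pd.Series]:
    """Per-species proteome size metrics and cohort totals.

    Each species maps either to a list of protein lengths (FASTA-derived) or
    to an AnnotationSet (gene/transcript counts only). Returns the
    per-species table and a totals row summing the count columns.
    """
    rows = {}
    for species in sorted(species_data):
        data = species_data[species]
        if isinstance(data, AnnotationSet):
            rows[species] = {
                "gene_count": data.n_genes,
                "transcript_count": data.n_transcripts,
                "protein_count": data.n_transcripts,
                "mean_protein_len": float("nan"),
                "max_protein_len": float("nan"),
            }
        else:
            lengths = list(data)
            rows[species] = {
                "gene_count": float("nan"),
                "transcript_count": float("nan"),
                "protein_count": len(lengths),
                "mean_protein_len": float(np.mean(lengths)) if lengths else 0.0,
                "max_protein_len": float(max(lengths)) if lengths else 0.0,
            }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "species"
    totals = table[["gene_count", "transcript_count", "protein_count"]].sum(
        min_count=1
    )
    return table, totals
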