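"""Tag-count normalization and expression-state selection.

The input is a gene x condition table of 3'-tag counts over the three
pooled libraries (normal, tumor, regressed).  Because each transcript
contributes one tag, TPM normalization is counts-per-million without a
length term.  Presence/absence is a tri-state call: a gene can be present
(TPM above threshold), absent (raw count at or below a ceiling), or
ambiguous; ambiguous genes never enter the candidate set.  Candidates are
genes present in tumor AND regressed but absent in normal — the
tumor-and-regression-expressed selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_CONDITIONS = ("normal", "tumor", "regressed")

log = logging.getLogger(__name__)


class ExpressionError(ValueError):
    pass


@dataclass(frozen=True)
class PresenceThresholds:
    """tau_present: minimum TPM to call a gene present; tau_absent: maximum
    raw tag count to call it absent.  Defaults: present at >= 1 TPM, absent
    only at literally zero tags."""
    tau_present: float = 1.0
    tau_absent: int = 0

    def __post_init__(self):
        if self.tau_present <= 0:
            raise ExpressionError("tau_present must be > 0")
        if self.tau_absent < 0:
            raise ExpressionError("tau_absent must be >= 0")


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()][0]
        raise ExpressionError(f"duplicate gene_id {dup!r}")
    missing = [c for c in REQUIRED_CONDITIONS if c not in counts.columns]
    if missing:
        raise ExpressionError(f"missing condition columns: {missing}")
    if not all(np.issubdtype(dt, np.integer) for dt in counts.dtypes):
        raise ExpressionError("tag counts must be integers (is this already TPM?)")
    if (counts.values < 0).any():
        r, c = np.argwhere(counts.values < 0)[0]
        raise ExpressionError(
            f"negative count for gene {counts.index[r]!r} in column "
            f"{counts.columns[c]!r}")
    return counts


def normalize_tpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-column counts-per-million: TPM_g = count_g / sum(counts) * 1e6.

    No transcript-length normalization is applied (one 3' tag per
    transcript).  Columns with zero total yield all-zero TPM with a logged
    warning.
    """
    validate_counts(counts)
    totals = counts.sum(axis=0)
    tpm = pd.DataFrame(0.0, index=counts.index, columns=counts.columns)
    for col in counts.columns:
        if totals[col] == 0:
            log.warning("column %r has zero total count; TPM set to 0", col)
            continue
        tpm[col] = counts[col] / totals[col] * 1e6
    return tpm


def call_presence(tpm: pd.DataFrame, counts: pd.DataFrame,
                  thresholds: PresenceThresholds = PresenceThresholds()
                  ) -> pd.DataFrame:
    """Tri-state call per gene x condition.

    present  iff TPM >= tau_present
    absent   iff raw count <= tau_absent (and not present)
    ambiguous otherwise
    """
    if not tpm.index.equals(counts.index) or not tpm.columns.equals(counts.columns):
        raise ExpressionError("tpm and counts tables must share gene/condition index")
    states = pd.DataFrame("ambiguous", index=tpm.index, columns=tpm.columns)
    states = states.where(~(tpm >= thresholds.tau_present), "present")
    absent_mask = (counts <= thresholds.tau_absent) & (tpm < thresholds.tau_present)
    states = states.where(~absent_mask, "absent")
    return states


def select_candidates(states: pd.DataFrame) -> set[str]:
    """Genes present in tumor AND regressed but absent in normal.

    An ambiguous state in any of the three conditions excludes the gene."""
    missing = [c for c in REQUIRED_CONDITIONS if c not in states.columns]
    if missing:
        raise ExpressionError(f"missing condition columns: {missing}")
    mask = ((states["normal"] == "absent")
            & (states["tumor"] == "present")
            & (states["regressed"] == "present"))
    return set(states.index[mask])


@dataclass
class MarkerQC:
    """Per-condition detection of housekeeping/pathway marker genes."""
    marker_tpm: pd.DataFrame
    detected_fraction: dict[str, float]
    flagged_conditions: list[str] = field(default_factory=list)


def marker_qc(tpm: pd.DataFrame, marker_genes: list[str],
              min_detected_fraction: float = 0.8) -> MarkerQC:
    """Transcriptome-coverage check against a marker panel (e.g. the 15
    gluconeogenesis genes): reports per-marker TPM and the fraction of
    markers with TPM > 0 per condition; flags conditions below the floor.

    Markers missing from the table count as undetected, not as errors.
    """
    if not marker_genes:
        raise ExpressionError("marker gene list is empty")
    sub = tpm.reindex(marker_genes).fillna(0.0)
    frac = {col: float((sub[col] > 0).mean()) for col in tpm.columns}
    flagged = sorted(c for c, f in frac.items() if f < min_detected_fraction)
    return MarkerQC(marker_tpm=sub, detected_fraction=frac,
                    flagged_conditions=flagged)


def read_counts_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_tsv(table: pd.DataFrame, path: str):
    table.to_csv(path, sep="\t")
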