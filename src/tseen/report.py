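"""Final statistics and audit outputs: the 2x2 conservation test, the
flow-diagram summary, and a deterministic machine-readable result bundle.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, asdict

import numpy as np
from scipy.special import erfc

log = logging.getLogger(__name__)


class ReportError(ValueError):
    pass


@dataclass
class ContingencyResult:
    a: int
    b: int
    c: int
    d: int
    chi2: float
    p: float
    proportion_study: float       # a / (a + b)
    proportion_comparison: float  # c / (c + d)


def chisq_2x2(a: int, b: int, c: int, d: int,
              continuity: bool = False) -> ContingencyResult:
    """Pearson chi-square for a 2x2 table, 1 df, upper tail.

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)), N = a+b+c+d.  No Yates
    continuity correction by default.  The upper-tail p of chi2(1) is
    computed as erfc(sqrt(chi2 / 2)), numerically stable below 1e-300.

    Row 1 is the study set (with / without reference ortholog), row 2 the
    comparison set.  The comparison row may overlap the study row — for a
    conservation contrast of a study subset against all novel genes, the
    full novel-gene marginals are used as row 2 as printed.
    """
    if min(a, b, c, d) < 0:
        raise ReportError("counts must be >= 0")
    if a + b == 0 or c + d == 0:
        raise ReportError("zero row sum")
    N = a + b + c + d
    col1, col2 = a + c, b + d
    if col1 == 0 or col2 == 0:
        log.warning("zero column sum; chi2 set to 0")
        chi2 = 0.0
    else:
        num = abs(a * d - b * c)
        if continuity:
            num = max(0.0, num - N / 2)
        chi2 = N * num * num / ((a + b) * (c + d) * col1 * col2)
    p = float(erfc(np.sqrt(chi2 / 2.0))) if chi2 > 0 else 1.0
    return ContingencyResult(a, b, c, d, float(chi2), p,
                             a / (a + b), c / (c + d))


STAGES = ("selected", "stable_id", "novel", "novel_with_reference_orthologs",
          "reference_ortholog_total")


@dataclass
class FlowSummary:
    """Fig-1-style node counts per method.  Focal-gene nodes are
    non-increasing; the reference-ortholog total may exceed its parent node
    through duplication fan-out."""
    per_method: dict[str, dict[str, int]]

    def to_json(self) -> str:
        return json.dumps({"stages": list(STAGES),
                           "per_method": self.per_method},
                          sort_keys=True, indent=1)


def flow_summary(stage_counts: dict[str, dict[str, int]]) -> FlowSummary:
    """Validate and package per-method stage counts.

    ``stage_counts`` maps method -> {stage -> count}; every stage in
    :data:`STAGES` must be present for every method.
    """
    for method, counts in stage_counts.items():
        missing = [s for s in STAGES if s not in counts]
        if missing:
            raise ReportError(
                f"method {method!r} is missing stages: {missing}")
        focal_nodes = [counts[s] for s in STAGES[:-1]]
        if any(x < y for x, y in zip(focal_nodes, focal_nodes[1:])):
            raise ReportError(
                f"focal-gene stage counts must be non-increasing "
                f"({method!r}: {focal_nodes})")
    return FlowSummary(per_method={m: dict(c) for m, c in
                                   sorted(stage_counts.items())})


def write_report(results: dict, outdir: str) -> dict:
    """Write every result table/JSON into ``outdir`` and return a manifest
    listing each file with its line count.  Same inputs give identical
    manifests (no timestamps in content)."""
    os.makedirs(outdir, exist_ok=True)
    manifest: dict[str, dict] = {}

    def emit(name: str, text: str):
        path = os.path.join(outdir, name)
        with open(path, "w") as fh:
            fh.write(text)
        manifest[name] = {"lines": text.count("\n")}

    if "flow" in results:
        emit("flow_summary.json", results["flow"].to_json() + "\n")
    if "conservation" in results:
        emit("conservation_test.json",
             json.dumps(asdict(results["conservation"]), sort_keys=True,
                        indent=1) + "\n")
    for name in ("tseen_records", "ortholog_calls", "gain_records",
                 "enrichment"):
        if name in results and results[name] is not None:
            emit(f"{name}.tsv", results[name])
        else:
            manifest[f"{name}.tsv"] = {"absent": True}
    emit("manifest.json", json.dumps(manifest, sort_keys=True, indent=1) + "\n")
    return manifest
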