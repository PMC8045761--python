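"""Assembly of the eight regulated gene sets from contrast results.

Cold sets (per fraction): a gene is cold-regulated in a mutant-dependent way
when the wild type responds to cold (|signed fold| >= fold_min, expressed,
significant) while the mutant does not (expressed, |signed fold| <= fold_min —
no significance requirement on the non-responder side). Translational sets
are computed on the polysomal fraction and then purged of every gene that is
transcriptionally regulated (total-RNA sets, up or down), so that a change in
polysome loading driven purely by transcript abundance is not mistaken for
translational control.

Normal-temperature sets contrast mutant vs wild type within the control
condition, one fraction at a time, with the same exclusion applied to the
polysomal side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .contrasts import ContrastResult, Thresholds, summarize_contrast
from .io import Condition, DesignCell, Fraction, Genotype, SignalMatrix

__all__ = [
    "Direction",
    "GeneSetLabel",
    "ResponseCall",
    "GeneSetAssignment",
    "classify_response",
    "nonresponder",
    "cold_atgcn1_sets",
    "exclude_transcriptional",
    "nt_genotype_sets",
    "assemble_gene_sets",
    "assignments_from_sets",
    "write_gene_sets",
]


class Direction(str, Enum):
    UP = "UP"
    DOWN = "DOWN"
    NONE = "NONE"


class GeneSetLabel(str, Enum):
    COLD_DOWN_TX = "COLD_DOWN_TX"
    COLD_UP_TX = "COLD_UP_TX"
    COLD_DOWN_TL = "COLD_DOWN_TL"
    COLD_UP_TL = "COLD_UP_TL"
    NT_UP_TX = "NT_UP_TX"
    NT_DOWN_TX = "NT_DOWN_TX"
    NT_UP_TL = "NT_UP_TL"
    NT_DOWN_TL = "NT_DOWN_TL"


@dataclass(frozen=True)
class ResponseCall:
    gene_id: str
    direction: Direction
    significant: bool
    expressed: bool


@dataclass(frozen=True)
class GeneSetAssignment:
    gene_id: str
    labels: frozenset[GeneSetLabel]


def _significant(result: ContrastResult, thresholds: Thresholds) -> bool:
    metric = result.q if thresholds.sig_metric == "q" else result.p
    return metric < thresholds.alpha


def classify_response(
    result: ContrastResult,
    thresholds: Thresholds,
    *,
    grant_significance: bool = False,
) -> ResponseCall:
    """Call UP/DOWN/NONE for one gene in one contrast.

    UP requires signed fold >= fold_min, the expression filter, and
    significance (q or p < alpha per ``thresholds.sig_metric``); DOWN is the
    mirror image. ``grant_significance`` waives the significance requirement
    (used with noise-free replicate data, where the test is degenerate).
    A missing fold always yields NONE; the audit flags are still filled in.
    """
    sig = grant_significance or _significant(result, thresholds)
    if not result.complete:
        return ResponseCall(result.gene_id, Direction.NONE, sig, result.expressed)
    direction = Direction.NONE
    if result.expressed and sig:
        if result.signed_fold >= thresholds.fold_min:
            direction = Direction.UP
        elif result.signed_fold <= -thresholds.fold_min:
            direction = Direction.DOWN
    return ResponseCall(result.gene_id, direction, sig, result.expressed)


def nonresponder(result: ContrastResult, thresholds: Thresholds) -> bool:
    """True iff the gene is expressed and its |signed fold| stays within fold_min.

    No significance requirement: non-response is defined purely by expression
    and a bounded fold, mirroring the selection criterion for the mutant side.
    Genes with a missing fold are not classifiable as non-responders.
    """
    if not result.complete:
        return False
    return result.expressed and abs(result.signed_fold) <= thresholds.fold_min


def _check_universe(a: Sequence[ContrastResult], b: Sequence[ContrastResult]) -> None:
    ga = {r.gene_id for r in a}
    gb = {r.gene_id for r in b}
    if ga != gb:
        diff = sorted(ga.symmetric_difference(gb))
        raise ValueError(
            f"contrasts cover different gene universes; symmetric difference "
            f"({len(diff)} genes): {diff[:10]}"
        )


def cold_atgcn1_sets(
    wt: Sequence[ContrastResult],
    mut: Sequence[ContrastResult],
    thresholds: Thresholds = Thresholds(),
    *,
    grant_significance: bool = False,
) -> tuple[set[str], set[str]]:
    """(down, up) gene sets: wild-type responders whose mutant counterpart is flat.

    Membership in DOWN: the wild-type call is DOWN and the mutant is a
    non-responder; UP analogously. The two sets are disjoint by construction.
    """
    _check_universe(wt, mut)
    mut_by_gene = {r.gene_id: r for r in mut}
    down: set[str] = set()
    up: set[str] = set()
    for result in wt:
        call = classify_response(result, thresholds, grant_significance=grant_significance)
        if call.direction is Direction.NONE:
            continue
        if nonresponder(mut_by_gene[result.gene_id], thresholds):
            (down if call.direction is Direction.DOWN else up).add(result.gene_id)
    return down, up


def exclude_transcriptional(
    translational_sets: tuple[set[str], set[str]],
    transcriptional_regulated: set[str],
) -> tuple[set[str], set[str]]:
    """Remove transcriptionally regulated genes from both translational sets."""
    down, up = translational_sets
    return down - transcriptional_regulated, up - transcriptional_regulated


def nt_genotype_sets(
    results: Sequence[ContrastResult],
    thresholds: Thresholds = Thresholds(),
    *,
    transcriptional_regulated: set[str] | None = None,
    grant_significance: bool = False,
) -> tuple[set[str], set[str]]:
    """(up_in_mut, down_in_mut) from a mutant-vs-WT contrast within one condition.

    ``results`` must come from a contrast with the wild-type cell as reference
    and the mutant cell as alternative. For the polysomal fraction, pass the
    union of the total-RNA regulated sets of the same genotype contrast as
    ``transcriptional_regulated`` to apply the transcription-exclusion rule.
    """
    up: set[str] = set()
    down: set[str] = set()
    for result in results:
        call = classify_response(result, thresholds, grant_significance=grant_significance)
        if call.direction is Direction.UP:
            up.add(result.gene_id)
        elif call.direction is Direction.DOWN:
            down.add(result.gene_id)
    if transcriptional_regulated is not None:
        down, up = exclude_transcriptional((down, up), transcriptional_regulated)
    return up, down


def assemble_gene_sets(
    matrix: SignalMatrix,
    thresholds: Thresholds = Thresholds(),
    *,
    pseudocount: float = 1.0,
    expr_basis: str = "mean_sum",
    test: str = "pooled",
    grant_significance: bool = False,
) -> tuple[dict[GeneSetLabel, set[str]], dict[str, list[ContrastResult]]]:
    """Run all six contrasts and assemble the eight labelled gene sets.

    Returns the label -> gene-set mapping and the underlying contrast results
    keyed by a descriptive contrast name (for reporting and export).
    """
    def cell(g: Genotype, c: Condition, f: Fraction) -> DesignCell:
        return DesignCell(g, c, f)

    kwargs = dict(pseudocount=pseudocount, expr_basis=expr_basis, test=test)
    contrasts = {
        "wt_cold_total": summarize_contrast(
            matrix, cell(Genotype.WT, Condition.CK, Fraction.TOTAL),
            cell(Genotype.WT, Condition.COLD, Fraction.TOTAL), thresholds, **kwargs),
        "mut_cold_total": summarize_contrast(
            matrix, cell(Genotype.MUT, Condition.CK, Fraction.TOTAL),
            cell(Genotype.MUT, Condition.COLD, Fraction.TOTAL), thresholds, **kwargs),
        "wt_cold_poly": summarize_contrast(
            matrix, cell(Genotype.WT, Condition.CK, Fraction.POLY),
            cell(Genotype.WT, Condition.COLD, Fraction.POLY), thresholds, **kwargs),
        "mut_cold_poly": summarize_contrast(
            matrix, cell(Genotype.MUT, Condition.CK, Fraction.POLY),
            cell(Genotype.MUT, Condition.COLD, Fraction.POLY), thresholds, **kwargs),
        "nt_genotype_total": summarize_contrast(
            matrix, cell(Genotype.WT, Condition.CK, Fraction.TOTAL),
            cell(Genotype.MUT, Condition.CK, Fraction.TOTAL), thresholds, **kwargs),
        "nt_genotype_poly": summarize_contrast(
            matrix, cell(Genotype.WT, Condition.CK, Fraction.POLY),
            cell(Genotype.MUT, Condition.CK, Fraction.POLY), thresholds, **kwargs),
    }

    tx_down, tx_up = cold_atgcn1_sets(
        contrasts["wt_cold_total"], contrasts["mut_cold_total"], thresholds,
        grant_significance=grant_significance)
    tl_down, tl_up = cold_atgcn1_sets(
        contrasts["wt_cold_poly"], contrasts["mut_cold_poly"], thresholds,
        grant_significance=grant_significance)
    tl_down, tl_up = exclude_transcriptional((tl_down, tl_up), tx_down | tx_up)

    nt_tx_up, nt_tx_down = nt_genotype_sets(
        contrasts["nt_genotype_total"], thresholds,
        grant_significance=grant_significance)
    nt_tl_up, nt_tl_down = nt_genotype_sets(
        contrasts["nt_genotype_poly"], thresholds,
        transcriptional_regulated=nt_tx_up | nt_tx_down,
        grant_significance=grant_significance)

    sets = {
        GeneSetLabel.COLD_DOWN_TX: tx_down,
        GeneSetLabel.COLD_UP_TX: tx_up,
        GeneSetLabel.COLD_DOWN_TL: tl_down,
        GeneSetLabel.COLD_UP_TL: tl_up,
        GeneSetLabel.NT_UP_TX: nt_tx_up,
        GeneSetLabel.NT_DOWN_TX: nt_tx_down,
        GeneSetLabel.NT_UP_TL: nt_tl_up,
        GeneSetLabel.NT_DOWN_TL: nt_tl_down,
    }
    return sets, contrasts


def assignments_from_sets(
    sets: Mapping[GeneSetLabel, set[str]], universe: Iterable[str]
) -> list[GeneSetAssignment]:
    return [
        GeneSetAssignment(
            gene_id=g,
            labels=frozenset(lbl for lbl, members in sets.items() if g in members),
        )
        for g in universe
    ]


_SET_CONTRAST = {
    GeneSetLabel.COLD_DOWN_TX: ("wt_cold_total", "mut_cold_total"),
    GeneSetLabel.COLD_UP_TX: ("wt_cold_total", "mut_cold_total"),
    GeneSetLabel.COLD_DOWN_TL: ("wt_cold_poly", "mut_cold_poly"),
    GeneSetLabel.COLD_UP_TL: ("wt_cold_poly", "mut_cold_poly"),
    GeneSetLabel.NT_UP_TX: ("nt_genotype_total", None),
    GeneSetLabel.NT_DOWN_TX: ("nt_genotype_total", None),
    GeneSetLabel.NT_UP_TL: ("nt_genotype_poly", None),
    GeneSetLabel.NT_DOWN_TL: ("nt_genotype_poly", None),
}


def write_gene_sets(
    sets: Mapping[GeneSetLabel, set[str]],
    contrasts: Mapping[str, Sequence[ContrastResult]],
    out_dir: str | Path,
    annotations: Mapping[str, str] | None = None,
) -> list[Path]:
    """One TSV per label (gene, folds, p, q) plus a JSON count summary.

    ``annotations`` optionally maps gene_id -> functional category; when given
    it is joined on as an extra column (pre-supplied labels, never computed).
    """
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for label, members in sets.items():
        primary_name, secondary_name = _SET_CONTRAST[label]
        primary = {r.gene_id: r for r in contrasts[primary_name]}
        secondary = (
            {r.gene_id: r for r in contrasts[secondary_name]}
            if secondary_name
            else {}
        )
        rows = []
        for g in sorted(members):
            r = primary[g]
            row = {
                "gene_id": g,
                "wt_fold": r.signed_fold,
                "mut_fold": secondary[g].signed_fold if secondary else math.nan,
                "p": r.p,
                "q": r.q,
            }
            if annotations is not None:
                row["category"] = annotations.get(g, "")
            rows.append(row)
        frame = pd.DataFrame(
            rows,
            columns=["gene_id", "wt_fold", "mut_fold", "p", "q"]
            + (["category"] if annotations is not None else []),
        )
        path = out_dir / f"geneset_{label.value}.tsv"
        frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
        written.append(path)
    summary = {label.value: len(members) for label, members in sets.items()}
    summary_path = out_dir / "geneset_counts.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    written.append(summary_path)
    return written
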