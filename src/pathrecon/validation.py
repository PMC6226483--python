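"""Evidence overlay: clone and expression support for annotated proteins.

Annotated proteins are cross-checked against two independent evidence
sources: cloned sequences (accepted only when the clone's EC assignment
exactly equals one of the protein's annotated ECs) and expressed-gene
lists from transcriptome datasets (matched at the gene level, i.e. on
the gene part of the 12-digit protein identifier).  A protein counts as
*validated* when it is clone-supported or expressed in at least one
dataset; *multi-dataset* support means expression in two or more
distinct datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .model import PathwayDefinition, gene_of
from .reporting import percent

__all__ = [
    "CloneEvidence",
    "EvidenceOverlay",
    "apply_evidence",
    "support_summary",
    "read_clone_table",
    "read_expression_lists",
]


@dataclass(frozen=True)
class CloneEvidence:
    """A cloned sequence with its EC assignment."""

    protein_id: str
    ec: str
    accession: str = ""


@dataclass
class EvidenceOverlay:
    """Per-protein evidence flags over one pathway."""

    clone_supported: set[str] = field(default_factory=set)
    expression_support: dict[str, set[str]] = field(default_factory=dict)
    per_protein: dict[str, dict] = field(default_factory=dict)

    def n_expression_datasets(self, protein_id: str) -> int:
        return self.per_protein.get(protein_id, {}).get("n_expression_datasets", 0)

    def is_validated(self, protein_id: str) -> bool:
        flags = self.per_protein.get(protein_id)
        return bool(flags and (flags["clone"] or flags["n_expression_datasets"] >= 1))


def _pathway_proteins(p: PathwayDefinition) -> set[str]:
    return {pid for prots in p.ec_to_proteins.values() for pid in prots}


def apply_evidence(
    p: PathwayDefinition,
    clones: Iterable[CloneEvidence],
    expr: Mapping[str, set[str]],
) -> EvidenceOverlay:
    """Overlay clone and expression evidence on a pathway.

    ``expr`` maps dataset name -> set of supported identifiers; entries
    may be gene ids or 12-digit protein ids (reduced to their gene
    part).  Clone support requires exact EC equality with one of the
    protein's annotated ECs.
    """
    if len(set(expr)) != len(list(expr)):
        raise ValueError("expression dataset names must be unique")
    proteins = _pathway_proteins(p)
    overlay = EvidenceOverlay()
    for c in clones:
        if c.protein_id in proteins and c.ec in p.ecs_of_protein(c.protein_id):
            overlay.clone_supported.add(c.protein_id)
    gene_sets = {name: {gene_of(x) for x in ids} for name, ids in expr.items()}
    for name, genes in gene_sets.items():
        overlay.expression_support[name] = {
            pid for pid in proteins if gene_of(pid) in genes
        }
    for pid in proteins:
        n_expr = sum(pid in s for s in overlay.expression_support.values())
        overlay.per_protein[pid] = {
            "clone": pid in overlay.clone_supported,
            "n_expression_datasets": n_expr,
        }
    return overlay


def support_summary(o: EvidenceOverlay, p: PathwayDefinition) -> pd.DataFrame:
    """Per-sub-metabolism (plus overall) support report.

    Columns give counts and percentages for clone support, expression
    support (>= 1 dataset), multi-dataset support (>= 2), and the
    validated union.  Percentages are reported rounded half-up to
    integers (the raw fractions stay available as ``*_pct_raw``);
    denominators are the sub-metabolism's protein count, and the total
    unique protein count for the overall row.  Multi-dataset share is
    emitted against both plausible denominators (expression-supported
    proteins and all proteins), labelled accordingly.
    """
    rows = []
    subs = p.subs_present()
    for name in [*subs, "Total"]:
        if name == "Total":
            prots = _pathway_proteins(p)
        else:
            ecs = {
                ec
                for r in p.reactions_in(name)
                if r.rtype in ("enzymatic", "spontaneous")
                for ec in r.ec_numbers
            }
            prots = {pid for ec in ecs for pid in p.ec_to_proteins.get(ec, set())}
        n = len(prots)
        n_clone = len(prots & o.clone_supported)
        n_expr = sum(o.n_expression_datasets(pid) >= 1 for pid in prots)
        n_multi = sum(o.n_expression_datasets(pid) >= 2 for pid in prots)
        n_valid = sum(o.is_validated(pid) for pid in prots)
        row = {
            "sub_metabolism": name,
            "n_proteins": n,
            "n_clone": n_clone,
            "n_expression": n_expr,
            "n_multi_dataset": n_multi,
            "n_validated": n_valid,
        }
        for key, num in [
            ("clone", n_clone),
            ("expression", n_expr),
            ("validated", n_valid),
        ]:
            row[f"{key}_pct"] = percent(num, n)
            row[f"{key}_pct_raw"] = 100.0 * num / n if n else 0.0
        row["multi_dataset_pct_of_expressed"] = percent(n_multi, n_expr)
        row["multi_dataset_pct_of_all"] = percent(n_multi, n)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O


def read_clone_table(path) -> list[CloneEvidence]:
    """Clone table TSV with columns protein_id, ec, genbank_accession."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        CloneEvidence(row.protein_id, row.ec, getattr(row, "genbank_accession", ""))
        for row in df.itertuples()
    ]


def read_expression_lists(paths: Mapping[str, str]) -> dict[str, set[str]]:
    """One identifier-list TSV per dataset (first column is the gene or
    protein id); dataset names are the mapping keys."""
    out: dict[str, set[str]] = {}
    for name, path in paths.items():
        df = pd.read_csv(path, sep="\t", dtype=str)
        out[name] = set(df.iloc[:, 0].dropna())
    return out
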