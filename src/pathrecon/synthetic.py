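"""Self-contained synthetic scenarios with planted ground truth.

A scenario emulates the six-template comparative reconstruction design:
a master catalogue of reactions over the eight sub-metabolisms, template
species that each carry a configurable shared fraction of it, template
proteomes, and a query proteome whose proteins are mutated copies of
template enzymes at controlled sequence identity.  Gaps are planted by
withholding query orthologs for selected enzymes, and clone/expression
evidence sets are drawn with configurable coverage fractions.  The
generator records everything it plants (ortholog pairs, annotations
with supporter sets, gap/orphan reactions, expected Hamming distances,
evidence memberships) so recovery tests can demand exact agreement.

Design notes:

* The query pre-pathway is assembled as the union of template
  reactions, so the first template defaults to shared fraction 1.0
  (the "well-annotated model plant"); the whole master catalogue is
  then covered and every other template's planted Hamming distance is
  exactly 1 - its shared fraction.  Should no template cover a
  reaction, it is force-added to the best-covered template and the
  recorded ground truth reflects the realized sets.
* A template species that catalogues an enzyme without supporting the
  query's annotation carries no protein for it (a reaction reference
  only), so planted supporter sets — hence conservation scores — are
  exact by construction.
* Substitutions are drawn uniformly over the 19 alternative residues at
  distinct positions, with no indels in the default mode, so sequence
  identity alone controls filter outcomes and coverage stays at 100.
"""

from __future__ import annotations

import dataclasses
import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .model import (
    SUB_METABOLISMS,
    CurationRecord,
    GapFill,
    PathwayDefinition,
    Reaction,
)
from .validation import CloneEvidence

__all__ = ["ScenarioConfig", "GroundTruth", "Scenario", "generate_scenario", "mutate_to_identity"]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_DEFAULT_REACTIONS_PER_SUB = {
    "CAL": 8, "SUC": 6, "STA": 6, "RES": 10, "AMI": 12, "CEL": 5, "FAT": 6, "NUC": 7,
}
_DEFAULT_SHARED_FRACTION = {
    "arabidopsis": 1.0, "turnip": 0.9, "maize": 0.8,
    "rice": 0.8, "castor_bean": 0.85, "potato": 0.9,
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Knobs of the synthetic study design.

    Defaults mirror a desk-scale version of the six-template study:
    six templates, all eight sub-metabolisms (~60 reactions), ortholog
    identities well above the 60% filter, four planted gaps (three in
    amino acid and one in nucleotide biosynthesis), a right-skewed
    supporter-count distribution, ~5% clone coverage concentrated at
    exact EC matches, and six expression datasets with decreasing
    coverage whose union supports most genes.
    """

    seed: int = 0
    template_names: tuple[str, ...] = (
        "arabidopsis", "turnip", "maize", "rice", "castor_bean", "potato",
    )
    reactions_per_sub: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_REACTIONS_PER_SUB)
    )
    spontaneous_per_sub: Mapping[str, int] = field(
        default_factory=lambda: {"CAL": 1, "NUC": 1}
    )
    shared_fraction: float | Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SHARED_FRACTION)
    )
    planted_gaps: Mapping[str, int] = field(
        default_factory=lambda: {"AMI": 3, "NUC": 1}
    )
    supporter_count_probs: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.25, 2: 0.20, 3: 0.18, 4: 0.15, 5: 0.12, 6: 0.10}
    )
    isoform_count_probs: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.55, 2: 0.25, 3: 0.12, 4: 0.08}
    )
    isoform_same_gene_prob: float = 0.25
    seq_length_range: tuple[int, int] = (80, 150)
    ortholog_identity_range: tuple[float, float] = (75.0, 95.0)
    below_threshold_fraction: float = 0.0
    below_threshold_identity: float = 50.0
    ec_reuse_prob: float = 0.12
    two_ec_prob: float = 0.05
    cross_sub_prob: float = 0.05
    decoy_fraction: float = 0.3
    clone_fraction: float = 0.05
    clone_ec_mismatch_fraction: float = 0.0
    expression_fractions: tuple[float, ...] = (0.7, 0.6, 0.5, 0.5, 0.4, 0.3)

    def validate(self) -> None:
        for name, frac in [
            ("below_threshold_fraction", self.below_threshold_fraction),
            ("decoy_fraction", self.decoy_fraction),
            ("clone_fraction", self.clone_fraction),
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for f in self.expression_fractions:
            if not 0.0 <= f <= 1.0:
                raise ValueError("expression fractions must lie in [0, 1]")
        lo, hi = self.ortholog_identity_range
        if not (0 < lo <= hi <= 100):
            raise ValueError("ortholog identity targets must lie in (0, 100]")
        for sub, n in self.planted_gaps.items():
            if n > self.reactions_per_sub.get(sub, 0):
                raise ValueError(f"more planted gaps than reactions in {sub}")
        if any(n < 0 for n in self.reactions_per_sub.values()):
            raise ValueError("reaction counts must be >= 0")

    def fraction_for(self, template: str) -> float:
        if isinstance(self.shared_fraction, Mapping):
            return float(self.shared_fraction[template])
        return float(self.shared_fraction)


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed for exact recovery checks."""

    ortholog_pairs: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    annotations: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)
    below_threshold_pairs: set[tuple[str, str]] = field(default_factory=set)
    gap_reaction_ids: list[str] = field(default_factory=list)
    orphan_reaction_ids: list[str] = field(default_factory=list)
    hd: dict[tuple[str, str], float] = field(default_factory=dict)
    hd_overall: dict[str, float] = field(default_factory=dict)
    clone_supported: set[str] = field(default_factory=set)
    expression: dict[str, set[str]] = field(default_factory=dict)

    def cs_of(self, protein: str, ec: str, n_templates: int) -> float:
        return len(self.annotations[(protein, ec)]) / n_templates


@dataclass
class Scenario:
    """An in-memory scenario bundle."""

    config: ScenarioConfig
    query_proteome: dict[str, str]
    template_proteomes: dict[str, dict[str, str]]
    template_pathways: dict[str, PathwayDefinition]
    master: PathwayDefinition
    curation: CurationRecord
    clones: list[CloneEvidence]
    expression: dict[str, set[str]]
    truth: GroundTruth

    @property
    def scope(self) -> set[str]:
        return {s for r in self.master.reactions.values() for s in r.sub_metabolisms}

    def write_bundle(self, out_dir) -> None:
        """Write the bundle directory layout (FASTA proteomes, pathway
        JSON, curation YAML, evidence TSVs, truth and manifest)."""
        from .model import write_pathway
        from .reconstruction import write_curation_record

        out = Path(out_dir)
        (out / "templates").mkdir(parents=True, exist_ok=True)
        (out / "pathways").mkdir(exist_ok=True)
        (out / "evidence").mkdir(exist_ok=True)
        _write_fasta(self.query_proteome, out / "query.faa")
        for k, proteome in self.template_proteomes.items():
            _write_fasta(proteome, out / "templates" / f"{k}.faa")
        for k, pathway in self.template_pathways.items():
            write_pathway(pathway, out / "pathways" / f"{k}.json")
        write_curation_record(self.curation, out / "curation.yaml")
        with open(out / "evidence" / "clones.tsv", "w") as fh:
            fh.write("protein_id\tec\tgenbank_accession\n")
            for c in self.clones:
                fh.write(f"{c.protein_id}\t{c.ec}\t{c.accession}\n")
        for name, genes in self.expression.items():
            with open(out / "evidence" / f"expr_{name}.tsv", "w") as fh:
                fh.write("gene_id\n")
                for g in sorted(genes):
                    fh.write(g + "\n")
        with open(out / "truth.json", "w") as fh:
            json.dump(_truth_to_json(self.truth), fh, indent=1)
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(
                {"seed": self.config.seed, "config": _config_to_json(self.config)},
                fh, sort_keys=False,
            )


def _write_fasta(proteome: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for pid in proteome:
            fh.write(f">{pid}\n{proteome[pid]}\n")


def _config_to_json(cfg: ScenarioConfig) -> dict:
    doc = dataclasses.asdict(cfg)
    return json.loads(json.dumps(doc))


def _truth_to_json(t: GroundTruth) -> dict:
    return {
        "ortholog_pairs": {k: sorted(map(list, v)) for k, v in t.ortholog_pairs.items()},
        "annotations": [
            {"protein": p, "ec": ec, "supporters": sorted(s)}
            for (p, ec), s in sorted(t.annotations.items())
        ],
        "below_threshold_pairs": sorted(map(list, t.below_threshold_pairs)),
        "gap_reaction_ids": t.gap_reaction_ids,
        "orphan_reaction_ids": t.orphan_reaction_ids,
        "hd": [
            {"sub_metabolism": j, "template": k, "hd": v}
            for (j, k), v in sorted(t.hd.items())
        ],
        "hd_overall": dict(sorted(t.hd_overall.items())),
        "clone_supported": sorted(t.clone_supported),
        "expression": {k: sorted(v) for k, v in sorted(t.expression.items())},
    }


# ---------------------------------------------------------------------------
# Sequence mutation


def mutate_to_identity(seq: str, target_identity: float, rng: random.Random) -> str:
    """Substitute residues to reach a target column identity.

    Substitutions hit distinct positions (drawn without replacement)
    and replace the residue with one of the 19 alternatives, so the
    realized identity is exactly (L - n_sub) / L; it must land within
    +/- 2 percentage points of the target.  Sequences shorter than 10
    residues cannot be mutated reliably and raise.
    """
    if not 0 < target_identity <= 100:
        raise ValueError("target identity must lie in (0, 100]")
    if target_identity == 100:
        return seq
    if len(seq) < 10:
        raise ValueError("sequence too short (< 10 residues) for a controlled identity target")
    n_sub = round(len(seq) * (1 - target_identity / 100.0))
    realized = 100.0 * (len(seq) - n_sub) / len(seq)
    if abs(realized - target_identity) > 2.0:
        raise ValueError(
            f"target identity {target_identity} unreachable within 2 points "
            f"for length {len(seq)}"
        )
    positions = rng.sample(range(len(seq)), n_sub)
    out = list(seq)
    for pos in positions:
        out[pos] = rng.choice([a for a in AMINO_ACIDS if a != seq[pos]])
    return "".join(out)


def _draw(rng: random.Random, probs: Mapping[int, float]) -> int:
    keys = sorted(probs)
    return rng.choices(keys, weights=[probs[k] for k in keys])[0]


def _random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choices(AMINO_ACIDS, k=length))


# ---------------------------------------------------------------------------
# Scenario generation


def generate_scenario(cfg: ScenarioConfig) -> Scenario:
    """Generate a deterministic scenario bundle for a config.

    All randomness flows through one seeded source, so equal configs
    yield identical bundles.
    """
    cfg.validate()
    rng = random.Random(cfg.seed)

    # --- master reaction catalogue -------------------------------------
    master = PathwayDefinition(species="master")
    used_ecs: set[str] = set()
    ecs_by_sub: dict[str, list[str]] = {}
    primary_sub: dict[str, str] = {}

    def _new_ec() -> str:
        while True:
            ec = f"{rng.randint(1, 6)}.{rng.randint(1, 20)}.{rng.randint(1, 30)}.{rng.randint(1, 99)}"
            if ec not in used_ecs:
                used_ecs.add(ec)
                return ec

    rid_counter = 0
    reserved_gap_slots: dict[str, set[int]] = {}
    reserved_gap_rids: list[str] = []
    for sub in SUB_METABOLISMS:
        n = cfg.reactions_per_sub.get(sub, 0)
        n_spont = min(cfg.spontaneous_per_sub.get(sub, 0), n)
        n_gaps = cfg.planted_gaps.get(sub, 0)
        if n_gaps > n - n_spont:
            raise ValueError(f"infeasible config: {n_gaps} gaps exceed the "
                             f"enzymatic reactions of {sub}")
        # Gap reactions are reserved while the catalogue is built: they
        # keep a single fresh EC and a single membership so withholding
        # their ortholog gives exactly one gap each.
        reserved_gap_slots[sub] = set(rng.sample(range(n - n_spont), n_gaps))
        ecs_by_sub.setdefault(sub, [])
        for i in range(n):
            rid_counter += 1
            rid = f"R{rid_counter:05d}"
            spontaneous = i >= n - n_spont
            reserved = i in reserved_gap_slots[sub]
            subs = {sub}
            if not spontaneous and not reserved and rng.random() < cfg.cross_sub_prob:
                other = rng.choice([s for s in SUB_METABOLISMS if s != sub])
                subs.add(other)
            if spontaneous:
                ecs: set[str] = set()
            elif reserved:
                ecs = {_new_ec()}  # fresh EC, never reused or shared
            else:
                if ecs_by_sub[sub] and rng.random() < cfg.ec_reuse_prob:
                    ecs = {rng.choice(ecs_by_sub[sub])}
                else:
                    ec = _new_ec()
                    ecs = {ec}
                    ecs_by_sub[sub].append(ec)
                if rng.random() < cfg.two_ec_prob:
                    ec2 = _new_ec()
                    ecs.add(ec2)
                    ecs_by_sub[sub].append(ec2)
            master.add_reaction(
                Reaction(
                    reaction_id=rid,
                    ec_numbers=frozenset(ecs),
                    substrates=frozenset({f"M_{sub}_{i}"}),
                    products=frozenset({f"M_{sub}_{i + 1}"}),
                    sub_metabolisms=frozenset(subs),
                    rtype="spontaneous" if spontaneous else "enzymatic",
                )
            )
            primary_sub[rid] = sub
            if reserved:
                reserved_gap_rids.append(rid)

    # --- planted gaps (the reserved slots) ------------------------------
    gap_ids: list[str] = sorted(
        rid for rid in reserved_gap_rids
    )
    gap_ecs: set[str] = {
        ec for rid in gap_ids for ec in master.reactions[rid].ec_numbers
    }

    # --- template reaction complements ---------------------------------
    template_reactions: dict[str, set[str]] = {}
    enz_by_primary: dict[str, list[str]] = {}
    for rid, sub in primary_sub.items():
        if master.reactions[rid].rtype == "enzymatic":
            enz_by_primary.setdefault(sub, []).append(rid)
    spontaneous_ids = [
        r.reaction_id for r in master.reactions.values() if r.rtype == "spontaneous"
    ]
    for k in cfg.template_names:
        f = cfg.fraction_for(k)
        chosen: set[str] = set(spontaneous_ids)
        for sub in SUB_METABOLISMS:
            pool = sorted(enz_by_primary.get(sub, []))
            n_shared = round(f * len(pool))
            chosen |= set(rng.sample(pool, n_shared))
        template_reactions[k] = chosen
    # Guarantee union coverage of the master catalogue.
    best = max(cfg.template_names, key=cfg.fraction_for)
    covered = set().union(*template_reactions.values())
    for rid in master.reactions:
        if rid not in covered:
            template_reactions[best].add(rid)

    template_pathways = {
        k: PathwayDefinition(
            species=k,
            reactions={rid: master.reactions[rid] for rid in sorted(ids)},
        )
        for k, ids in template_reactions.items()
    }

    # --- proteins -------------------------------------------------------
    truth = GroundTruth(
        ortholog_pairs={k: set() for k in cfg.template_names},
        gap_reaction_ids=list(gap_ids),
    )
    query_proteome: dict[str, str] = {}
    template_proteomes: dict[str, dict[str, str]] = {k: {} for k in cfg.template_names}
    ec_templates: dict[str, list[str]] = {}
    for k, p in template_pathways.items():
        for ec in p.all_ecs():
            ec_templates.setdefault(ec, []).append(k)
    gene_counter = 0
    protein_counter = 0
    tprot_counter = 0
    max_supporters = max(cfg.supporter_count_probs)
    for ec in sorted(master.all_ecs()):
        if ec in gap_ecs:
            continue
        available = sorted(ec_templates.get(ec, []))
        if not available:
            continue
        n_iso = _draw(rng, cfg.isoform_count_probs)
        prev_gene: str | None = None
        for iso in range(n_iso):
            if prev_gene is not None and rng.random() < cfg.isoform_same_gene_prob:
                gene = prev_gene
            else:
                gene_counter += 1
                gene = f"{gene_counter:06d}"
            prev_gene = gene
            protein_counter += 1
            pid = f"{gene}_{protein_counter:06d}"
            m = min(_draw(rng, cfg.supporter_count_probs), len(available))
            supporters = sorted(rng.sample(available, m))
            length = rng.randint(*cfg.seq_length_range)
            base = _random_seq(rng, length)
            divergent = rng.random() < cfg.below_threshold_fraction
            if divergent:
                target = cfg.below_threshold_identity
            else:
                target = rng.uniform(*cfg.ortholog_identity_range)
            query_proteome[pid] = mutate_to_identity(base, target, rng)
            for k in supporters:
                tprot_counter += 1
                tpid = f"{k}|P{tprot_counter:05d}"
                template_proteomes[k][tpid] = base
                template_pathways[k].ec_to_proteins.setdefault(ec, set()).add(tpid)
                if divergent:
                    truth.below_threshold_pairs.add((pid, tpid))
                else:
                    truth.ortholog_pairs[k].add((pid, tpid))
            if not divergent:
                truth.annotations[(pid, ec)] = frozenset(supporters)

    # --- decoy proteins -------------------------------------------------
    for k in cfg.template_names:
        n_decoys = round(cfg.decoy_fraction * len(template_proteomes[k]))
        for i in range(n_decoys):
            template_proteomes[k][f"{k}|D{i + 1:04d}"] = _random_seq(
                rng, rng.randint(*cfg.seq_length_range)
            )

    # --- curation record ------------------------------------------------
    gaps_by_sub: dict[str, list[str]] = {}
    for rid in gap_ids:
        gaps_by_sub.setdefault(primary_sub[rid], []).append(rid)
    orphan_ids: list[str] = []
    for sub in SUB_METABOLISMS:
        if len(gaps_by_sub.get(sub, [])) >= 2:
            orphan_ids = [gaps_by_sub[sub][-1]]
            break
    fills = []
    for sub in SUB_METABOLISMS:
        for rid in gaps_by_sub.get(sub, []):
            if rid in orphan_ids:
                continue
            genes, prots = [], []
            for _ in range(2):
                gene_counter += 1
                protein_counter += 1
                genes.append(f"{gene_counter:06d}")
                prots.append(f"{gene_counter:06d}_{protein_counter:06d}")
            fills.append(
                GapFill(
                    reaction_id=rid,
                    ec=next(iter(master.reactions[rid].ec_numbers)),
                    proteins=tuple(prots),
                    genes=tuple(genes),
                    source_db_name="synthetic-curation-db",
                    sub_metabolism=sub,
                )
            )
    curation = CurationRecord(filled_gaps=tuple(fills), declared_orphans=tuple(orphan_ids))
    truth.orphan_reaction_ids = list(orphan_ids)

    # --- expected Hamming distances -------------------------------------
    enzymatic_final = [
        r.reaction_id
        for r in master.reactions.values()
        if r.rtype == "enzymatic" and r.reaction_id not in orphan_ids
    ]
    for k in cfg.template_names:
        present = template_reactions[k]
        for sub in SUB_METABOLISMS:
            universe = [
                rid for rid in enzymatic_final
                if sub in master.reactions[rid].sub_metabolisms
            ]
            if universe:
                truth.hd[(sub, k)] = sum(r not in present for r in universe) / len(universe)
        truth.hd_overall[k] = sum(r not in present for r in enzymatic_final) / len(
            enzymatic_final
        )

    # --- evidence sets ---------------------------------------------------
    all_query = sorted(query_proteome)
    fill_proteins = [p for f in fills for p in f.proteins]
    clone_pool = all_query + fill_proteins
    n_clones = round(cfg.clone_fraction * len(clone_pool))
    ec_of_protein: dict[str, str] = {p: ec for (p, ec) in truth.annotations}
    for f in fills:
        for p in f.proteins:
            ec_of_protein[p] = f.ec
    clones: list[CloneEvidence] = []
    cloneable = [p for p in clone_pool if p in ec_of_protein]
    for i, pid in enumerate(sorted(rng.sample(cloneable, min(n_clones, len(cloneable))))):
        mismatch = rng.random() < cfg.clone_ec_mismatch_fraction
        ec = _new_ec() if mismatch else ec_of_protein[pid]
        clones.append(CloneEvidence(pid, ec, f"SYN{i + 1:06d}"))
        if not mismatch:
            truth.clone_supported.add(pid)
    all_genes = sorted({pid.split("_")[0] for pid in clone_pool})
    expression: dict[str, set[str]] = {}
    for d, frac in enumerate(cfg.expression_fractions):
        name = f"dataset{d + 1}"
        expression[name] = set(rng.sample(all_genes, round(frac * len(all_genes))))
        truth.expression[name] = set(expression[name])

    return Scenario(
        config=cfg,
        query_proteome=query_proteome,
        template_proteomes=template_proteomes,
        template_pathways=template_pathways,
        master=master,
        curation=curation,
        clones=clones,
        expression=expression,
        truth=truth,
    )
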