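"""End-to-end orchestration of the four analysis modes.

``run_pipeline`` drives one mode from a :class:`RunConfig`:

* ``traditional`` — static columns only, parsimony with gaps as a fifth
  state, strict consensus + CI/RI (+ optional jackknife).
* ``bayesian`` — mixed models on the same static columns (paired-site model
  for stems, GTR+I+G for loops), MCMC, consensus with posterior
  probabilities, harmonic-mean lnL.
* ``standard_do`` — everything dynamic: per-regime DO tree searches over
  spliced blocks, ILD-based regime choice, sensitivity grid.
* ``constrained_do`` — static columns stay static, ambiguous regions go to
  DO under every regime, morphology reweighted per regime by the molecular
  tree-length ratio against regime 111, regime chosen by ILD, trees fused
  across regimes, Bremer supports on the final tree.

Everything is deterministic under the config seed; artifacts are written
as tab-separated tables and Newick files when an output directory is set.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import congruence, direct_opt, mcmc, parsimony, trees
from .alignments import (FragmentSet, MorphMatrix, StructuredAlignment,
                         write_newick)
from .annotation import (RegionAnnotation, StructureCharacter,
                         classify_regions, lump_terminal_raa)
from .models import (GTRIG, Paired7A, Paired16A, PartitionData,
                     encode_nucleotide_column, encode_pair_column)
from .congruence import IldTable, SensitivityGrid
from .direct_opt import CostRegime, DoScore, STANDARD_REGIMES
from .parsimony import (ParsimonyMatrix, SearchConfig, SearchResult,
                        heuristic_search, matrix_from_alignment,
                        matrix_from_morphology,
                        matrix_from_structure_characters, tree_fuse)
from .partitions import PartitionSet, build_partitions
from .synthetic import SimulationConfig, SyntheticDataset, simulate_dataset


@dataclass
class RunConfig:
    mode: str
    seed: int
    synthetic: SimulationConfig | None = None
    alignment: StructuredAlignment | None = None
    fragments: Sequence[FragmentSet] = ()
    morphology: MorphMatrix | None = None
    include_morphology: bool = False
    regimes: Sequence[CostRegime] = STANDARD_REGIMES
    search: SearchConfig = field(default_factory=SearchConfig)
    mcmc: mcmc.McmcConfig = field(default_factory=mcmc.McmcConfig)
    stem_model: str = "7A"
    monitored_clades: Mapping[str, frozenset] = field(default_factory=dict)
    ild_partitions: int = 2  # contiguous molecular partitions for ILD
    output_dir: str | None = None

    def __post_init__(self):
        if self.mode not in ("traditional", "bayesian", "standard_do",
                             "constrained_do"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class AnalysisResult:
    mode: str
    seed: int
    trees: list[trees.Node]
    consensus: trees.Node
    best_score: float | None = None
    ci: float | None = None
    ri: float | None = None
    ild_table: IldTable | None = None
    chosen_regime: str | None = None
    sensitivity: SensitivityGrid | None = None
    bremer: dict | None = None
    jackknife: dict | None = None
    posterior: mcmc.PosteriorSummary | None = None
    per_regime_results: dict | None = None
    partition_set: PartitionSet | None = None


def _load_data(cfg: RunConfig):
    if cfg.alignment is not None:
        return (cfg.alignment, list(cfg.fragments), cfg.morphology, [], None)
    sim = cfg.synthetic or SimulationConfig(seed=cfg.seed)
    ds = simulate_dataset(sim)
    # structure character is part of the evidence in structure-aware modes
    return (ds.alignment, [], cfg.morphology or ds.morphology,
            [ds.structure_character], ds)


def _annotate(aln: StructuredAlignment) -> RegionAnnotation:
    return lump_terminal_raa(aln, classify_regions(aln))


def _static_matrix(parts: PartitionSet) -> ParsimonyMatrix:
    return matrix_from_alignment(parts.alignment, parts.static_columns)


def _evidence_matrix(parts: PartitionSet,
                     include_morph: bool) -> ParsimonyMatrix:
    m = _static_matrix(parts)
    if parts.structure_characters:
        m = m.concat(matrix_from_structure_characters(
            parts.structure_characters, m.taxa))
    if include_morph and parts.morphology is not None:
        m = m.concat(matrix_from_morphology(parts.morphology, taxa=m.taxa))
    return m


def run_pipeline(cfg: RunConfig) -> AnalysisResult:
    aln, fragments, morphology, struct_chars, ds = _load_data(cfg)
    annotation = _annotate(aln)
    if cfg.mode == "traditional":
        result = _run_traditional(cfg, aln, annotation, morphology,
                                  struct_chars)
    elif cfg.mode == "bayesian":
        result = _run_bayesian(cfg, aln, annotation)
    elif cfg.mode == "standard_do":
        result = _run_do(cfg, aln, annotation, fragments, morphology,
                         struct_chars, constrained=False)
    else:
        result = _run_do(cfg, aln, annotation, fragments, morphology,
                         struct_chars, constrained=True)
    if cfg.output_dir:
        _write_artifacts(cfg, result)
    return result


def _run_traditional(cfg, aln, annotation, morphology, struct_chars
                     ) -> AnalysisResult:
    parts = build_partitions(aln, annotation, "traditional",
                             morphology=morphology if cfg.include_morphology
                             else None,
                             structure_characters=struct_chars)
    matrix = _evidence_matrix(parts, cfg.include_morphology)
    res = heuristic_search(matrix, config=cfg.search, seed=cfg.seed)
    cons = trees.strict_consensus(res.trees)
    ci, ri = parsimony.ci_ri(res.trees[0], matrix)
    return AnalysisResult(cfg.mode, cfg.seed, res.trees, cons,
                          best_score=res.best_score, ci=ci, ri=ri,
                          partition_set=parts)


def bayesian_partitions(aln: StructuredAlignment, annotation,
                        stem_model_kind: str = "7A"
                        ) -> list[PartitionData]:
    """Stem columns mapped to pair states under a paired-site model; loop
    columns under GTR+I+G."""
    parts = build_partitions(aln, annotation, "bayesian")
    partner = aln.partner()
    stem_cols = set(parts.static_stem_columns)
    bonds = [(i, j) for i, j in aln.pair_bonds()
             if i in stem_cols and j in stem_cols]
    out: list[PartitionData] = []
    if bonds:
        model = (Paired7A() if stem_model_kind == "7A" else Paired16A())
        partials = {}
        for t in aln.taxa:
            rows = [encode_pair_column([aln.sequences[t][i]],
                                       [aln.sequences[t][j]],
                                       list(model.states))[0]
                    for i, j in bonds]
            partials[t] = np.stack(rows)
        out.append(PartitionData(model, partials,
                                 column_ids=tuple(x for b in bonds
                                                  for x in b)))
    loop_cols = parts.static_loop_columns
    if loop_cols:
        model = GTRIG(p_invariant=0.1, gamma_shape=1.0)
        partials = {}
        for t in aln.taxa:
            col = [aln.sequences[t][c] for c in loop_cols]
            partials[t] = encode_nucleotide_column(col)
        out.append(PartitionData(model, partials,
                                 column_ids=tuple(loop_cols)))
    return out


def stem_model_candidates(aln: StructuredAlignment, annotation
                          ) -> dict[str, list[PartitionData]]:
    """The four model layouts compared by Bayes factors: a uniform
    nucleotide GTR+I+G, stem/loop-partitioned GTR+I+G, and the two mixed
    layouts pairing a GTR+I+G loop model with a 7- or 16-state paired-site
    stem model."""
    parts = build_partitions(aln, annotation, "bayesian")
    stem_cols = parts.static_stem_columns
    loop_cols = parts.static_loop_columns

    def nuc_partition(cols):
        partials = {t: encode_nucleotide_column(
            [aln.sequences[t][c] for c in cols]) for t in aln.taxa}
        return PartitionData(GTRIG(p_invariant=0.1, gamma_shape=1.0),
                             partials, column_ids=tuple(cols))

    out = {
        "uniform_gtr": [nuc_partition(stem_cols + loop_cols)],
        "partitioned_gtr": [nuc_partition(stem_cols),
                            nuc_partition(loop_cols)],
    }
    for label, kind in (("gtr_7a", "7A"), ("gtr_16a", "16A")):
        out[label] = bayesian_partitions(aln, annotation, kind)
    return out


def compare_stem_models(aln: StructuredAlignment, annotation,
                        tree: trees.Node, seed: int,
                        mcmc_config: mcmc.McmcConfig | None = None
                        ) -> dict[str, float]:
    """Harmonic-mean log marginal likelihood of the four model layouts on a
    fixed topology (branch lengths and model parameters sampled)."""
    cfg = mcmc_config or mcmc.McmcConfig(n_generations=4000,
                                         sample_every=20, n_runs=1,
                                         sample_topology=False)
    out = {}
    for label, partitions in stem_model_candidates(aln, annotation).items():
        traces = mcmc.run_mcmc(partitions, aln.taxa, cfg, seed=seed,
                               fixed_tree=tree)
        out[label] = mcmc.harmonic_mean_lnl(traces[0], cfg.burn_in)
    return out


def _run_bayesian(cfg, aln, annotation) -> AnalysisResult:
    partitions = bayesian_partitions(aln, annotation, cfg.stem_model)
    traces = mcmc.run_mcmc(partitions, aln.taxa, cfg.mcmc, seed=cfg.seed)
    summary = mcmc.consensus_and_pp(traces[0], aln.taxa,
                                    burn_in=cfg.mcmc.burn_in)
    return AnalysisResult(cfg.mode, cfg.seed, [summary.consensus],
                          summary.consensus, posterior=summary)


def _molecular_partition_lengths(parts: PartitionSet, regime,
                                 cfg: RunConfig, n_groups: int,
                                 ) -> dict[str, float]:
    """Best lengths of contiguous molecular partitions analysed alone (the
    ILD ingredients); groups approximate the per-gene split."""
    aln = parts.alignment
    out = {}
    static = parts.static_columns
    frags = list(parts.do_fragments)
    for g in range(n_groups):
        cols = [c for k, c in enumerate(static) if k % n_groups == g]
        gfrags = [f for k, f in enumerate(frags) if k % n_groups == g]
        sub = PartitionSet(mode=parts.mode if parts.mode == "constrained_do"
                           else parts.mode,
                           static_stem_columns=[c for c in cols
                                                if c in aln.partner()],
                           static_loop_columns=[c for c in cols
                                                if c not in aln.partner()],
                           do_fragments=gfrags,
                           alignment=aln) if parts.mode == "constrained_do" \
            else PartitionSet(mode="standard_do", do_fragments=gfrags,
                              alignment=aln)
        res = _do_search(sub, regime, cfg, morph_weight=0.0)
        out[f"part{g + 1}"] = res.best_score
    return out


def _do_search(parts: PartitionSet, regime, cfg: RunConfig,
               morph_weight: float = 1.0,
               include_morph: bool = False) -> SearchResult:
    static_m = _static_matrix(parts) if parts.static_columns else None
    struct_m = (matrix_from_structure_characters(parts.structure_characters,
                                                 parts.alignment.taxa)
                if parts.structure_characters else None)
    morph_m = (matrix_from_morphology(parts.morphology,
                                      taxa=parts.alignment.taxa)
               if include_morph and parts.morphology is not None else None)

    def score(tree) -> float:
        s = 0.0
        for frag in parts.do_fragments:
            s += direct_opt.tree_do_cost(tree, frag, regime, thorough=False)
        if static_m is not None:
            s += parsimony.fitch_length(tree, static_m, True)
        if struct_m is not None:
            s += parsimony.fitch_length(tree, struct_m, True)
        if morph_m is not None:
            s += morph_weight * parsimony.fitch_length(tree, morph_m, True)
        return s

    return heuristic_search(None, taxa=list(parts.alignment.taxa),
                            config=cfg.search, seed=cfg.seed, score_fn=score)


def _run_do(cfg, aln, annotation, fragments, morphology, struct_chars,
            constrained: bool) -> AnalysisResult:
    mode = "constrained_do" if constrained else "standard_do"
    anchors = () if constrained else _default_anchor_cuts(aln, annotation)
    parts = build_partitions(
        aln, annotation if constrained else annotation, mode,
        fragments=fragments,
        morphology=morphology if cfg.include_morphology else None,
        structure_characters=struct_chars if constrained else [],
        anchors=anchors)
    per_regime: dict[str, SearchResult] = {}
    mol_lengths: dict[str, float] = {}
    ild_table = IldTable()
    for regime in cfg.regimes:
        res = _do_search(parts, regime, cfg, morph_weight=0.0)
        per_regime[regime.label] = res
        mol_lengths[regime.label] = res.best_score
    base = mol_lengths.get("111", next(iter(mol_lengths.values())))
    results: dict[str, SearchResult] = {}
    for regime in cfg.regimes:
        weight = direct_opt.morphology_weight(mol_lengths[regime.label],
                                              base) if base else 1.0
        if cfg.include_morphology and parts.morphology is not None:
            res = _do_search(parts, regime, cfg, morph_weight=weight,
                             include_morph=True)
        else:
            res = per_regime[regime.label]
        results[regime.label] = res
        part_lengths = _molecular_partition_lengths(
            parts, regime, cfg, cfg.ild_partitions)
        if cfg.include_morphology and parts.morphology is not None:
            # morphology is its own ILD partition in combined analyses
            morph_m = matrix_from_morphology(parts.morphology,
                                             taxa=parts.alignment.taxa)
            morph_res = heuristic_search(morph_m, config=cfg.search,
                                         seed=cfg.seed)
            part_lengths["morphology"] = weight * morph_res.best_score
        ild_table.add(regime.label, res.best_score, part_lengths)
    chosen = congruence.select_regime(ild_table)
    chosen_res = results[chosen]
    # tree fusing across all regimes' optimal trees under the chosen regime
    pool = [t for r in results.values() for t in r.trees]
    chosen_regime_obj = next(r for r in cfg.regimes if r.label == chosen)
    weight = direct_opt.morphology_weight(mol_lengths[chosen], base) \
        if base else 1.0

    static_m = _static_matrix(parts) if parts.static_columns else None
    struct_m = (matrix_from_structure_characters(parts.structure_characters,
                                                 parts.alignment.taxa)
                if parts.structure_characters else None)
    morph_m = (matrix_from_morphology(parts.morphology,
                                      taxa=parts.alignment.taxa)
               if cfg.include_morphology and parts.morphology is not None
               else None)

    def final_score(tree, thorough=True):
        # searches use the single-pass DO variant; the final evaluation of
        # the few candidate trees affords the thorough one
        s = 0.0
        for frag in parts.do_fragments:
            s += direct_opt.tree_do_cost(tree, frag, chosen_regime_obj,
                                         thorough=thorough)
        if static_m is not None:
            s += parsimony.fitch_length(tree, static_m, True)
        if struct_m is not None:
            s += parsimony.fitch_length(tree, struct_m, True)
        if morph_m is not None:
            s += weight * parsimony.fitch_length(tree, morph_m, True)
        return s

    fused = tree_fuse(pool, final_score) if len(pool) > 1 else chosen_res
    final_trees = fused.trees
    cons = trees.strict_consensus(final_trees)
    grid = None
    if cfg.monitored_clades:
        grid = congruence.sensitivity_grid(
            {lab: r.trees for lab, r in results.items()},
            cfg.monitored_clades)
    brem = parsimony.bremer(final_trees, None,
                            config=SearchConfig(n_builds=1, swap="NNI"),
                            seed=cfg.seed,
                            score_fn=lambda t: final_score(t, False)) \
        if constrained else None
    return AnalysisResult(mode, cfg.seed, final_trees, cons,
                          best_score=fused.best_score,
                          ild_table=ild_table, chosen_regime=chosen,
                          sensitivity=grid, bremer=brem,
                          per_regime_results=results, partition_set=parts)


def _default_anchor_cuts(aln, annotation) -> dict:
    """Per-taxon cut coordinates for the standard (all-dynamic) analysis:
    raw sequences are spliced at the boundaries of the pre-aligned
    conserved blocks, the coordinate analogue of cutting at conserved
    anchor regions."""
    from .annotation import PRE
    from .partitions import strip_gaps
    bounds = sorted({iv.start for iv in annotation.intervals
                     if iv.kind != PRE} |
                    {iv.end for iv in annotation.intervals
                     if iv.kind != PRE})
    bounds = [b for b in bounds if 0 < b < aln.n_columns]
    cuts = {}
    for t in aln.taxa:
        seq = aln.sequences[t]
        pos = []
        for b in bounds:
            pos.append(len(strip_gaps(seq[:b])))
        cuts[t] = pos
    return cuts


def _write_artifacts(cfg: RunConfig, result: AnalysisResult) -> None:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_newick(result.trees, out / "best_trees.nwk")
    write_newick([result.consensus], out / "consensus.nwk", lengths=False)
    meta = {"mode": result.mode, "seed": result.seed,
            "best_score": result.best_score, "ci": result.ci,
            "ri": result.ri, "chosen_regime": result.chosen_regime}
    (out / "summary.json").write_text(json.dumps(meta, indent=2,
                                                 default=str) + "\n")
    if result.ild_table is not None:
        result.ild_table.to_frame().to_csv(out / "ild.tsv", sep="\t",
                                           index=False)
    if result.sensitivity is not None:
        result.sensitivity.to_frame().to_csv(out / "sensitivity.tsv",
                                             sep="\t")
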