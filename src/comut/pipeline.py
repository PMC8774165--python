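"""Configuration, validation, orchestration, and result serialization.

``run_pipeline`` ties the stages together over one set of input files:
summaries → pair enumeration → phenotype screens → survival screens →
functional analyses, writing one TSV per output plus a run manifest (config
echo, version, seed, per-file row counts and checksums).  Reruns with the
same inputs and config are byte-identical.  Cohorts at or below the
minimum size (50 by default) are excluded with a log entry.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .io import (
    MAF_COLUMNS,
    build_matrix,
    filter_synonymous,
    gene_mutation_frequency,
    read_gene_model,
    read_mutations,
)
from .impact import load_motifs, normalize_scores, scan_mutations, events_to_frame, panel_intersections
from .pairs import (
    classify_pair,
    cross_cohort_sharing,
    enumerate_gene_pairs,
    enumerate_position_pairs,
    pairs_to_frame,
)
from .phenotype import add_single_comparison, screen_phenotype, screen_single_genes_phenotype
from .summary import subject_loads, test_multimodality, top_frequent_genes
from .survival import burden_survival, comutation_adds_value, screen_single_genes, screen_survival

logger = logging.getLogger(__name__)

ALL_STAGES = ("summary", "enumerate", "phenotype", "survival", "functional")


@dataclass
class PipelineConfig:
    mutations: str
    genes: str
    outdir: str
    clinical: str | None = None
    expression: str | None = None
    drugs: str | None = None
    motifs: str | None = None
    reference: str | None = None
    impact_scores: str | None = None
    panels: dict = field(default_factory=dict)
    stages: tuple = ALL_STAGES
    min_freq: float = 0.10
    min_cohort_size: int = 51
    min_events: int = 10
    alpha: float = 0.05
    marginal_upper: float = 0.1
    tier_k: int = 1000
    min_fraction: float = 0.01
    top_n_genes: int = 20
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.min_freq <= 1.0:
            raise ValueError("min_freq must be in [0, 1]")
        if self.min_cohort_size <= 50:
            raise ValueError("min_cohort_size must be > 50")
        if not 0 < self.alpha <= self.marginal_upper <= 1:
            raise ValueError("need 0 < alpha <= marginal_upper <= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def validate_inputs(config: PipelineConfig) -> list[str]:
    """Schema report: missing columns, coordinate violations, allele problems.

    Returns an empty list iff all present inputs are valid.
    """
    violations: list[str] = []
    path = Path(config.mutations)
    if not path.exists():
        violations.append(f"mutations file not found: {path}")
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        mandatory = [c for c in MAF_COLUMNS if c != "cohort_id"]
        missing = [c for c in mandatory if c not in df.columns]
        if missing:
            violations.append(f"{path}: missing columns {missing}")
        else:
            pos = pd.to_numeric(df["position"], errors="coerce")
            bad = df.index[pos.isna() | (pos < 1)]
            for i in bad[:20]:
                violations.append(
                    f"{path}: row {i + 2}: position {df.loc[i, 'position']!r} "
                    "violates the 1-based coordinate rule"
                )
            same = df.index[df["ref_allele"] == df["alt_allele"]]
            for i in same[:20]:
                violations.append(f"{path}: row {i + 2}: ref_allele equals alt_allele")
    if not Path(config.genes).exists():
        violations.append(f"gene model not found: {config.genes}")
    if config.clinical:
        cpath = Path(config.clinical)
        if not cpath.exists():
            violations.append(f"clinical file not found: {cpath}")
        else:
            cdf = pd.read_csv(cpath, sep="\t")
            for col in ("subject_id", "time", "event"):
                if col not in cdf.columns:
                    violations.append(f"{cpath}: missing column {col}")
    return violations


def _write(df: pd.DataFrame, path: Path, manifest: dict, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, lineterminator="\n", float_format="%.6g")
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest["outputs"][path.name] = {"rows": int(len(df)), "sha256": digest}


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the enabled stages end to end; returns the output directory."""
    required = {"summary": [], "enumerate": [], "phenotype": ["clinical"],
                "survival": ["clinical"], "functional": []}
    for stage in config.stages:
        if stage not in ALL_STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        for need in required[stage]:
            if not getattr(config, need):
                raise ValueError(f"stage {stage!r} requires the {need} input")
    problems = validate_inputs(config)
    if problems:
        raise ValueError("invalid inputs:\n" + "\n".join(problems))

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        # outdir is excluded so reruns into different directories stay identical
        "config": {
            k: (dict(v) if isinstance(v, dict) else list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
            if k != "outdir"
        },
        "outputs": {},
        "log": [],
    }

    model = read_gene_model(config.genes)
    records = read_mutations(config.mutations, model)
    records = filter_synonymous(records, model)
    clinical = (
        pd.read_csv(config.clinical, sep="\t") if config.clinical else None
    )

    by_cohort: dict[str, list] = {}
    for rec in records:
        by_cohort.setdefault(rec.cohort_id or "ALL", []).append(rec)

    matrices, freqs, pair_lists = {}, {}, {}
    for cohort in sorted(by_cohort):
        recs = by_cohort[cohort]
        if clinical is not None and "cohort_id" in clinical.columns:
            subjects = sorted(clinical.loc[clinical["cohort_id"] == cohort, "subject_id"])
        else:
            subjects = sorted({r.subject_id for r in recs})
        if len(subjects) < config.min_cohort_size:
            msg = (f"cohort {cohort} excluded: {len(subjects)} subjects "
                   f"<= {config.min_cohort_size - 1}")
            logger.info(msg)
            manifest["log"].append(msg)
            continue
        matrices[cohort] = build_matrix(recs, subjects)
        freqs[cohort] = gene_mutation_frequency(matrices[cohort])

    if "summary" in config.stages and matrices:
        loads_by_cohort = {}
        for cohort, matrix in matrices.items():
            loads = subject_loads(matrix)
            loads_by_cohort[cohort] = loads["mutated_gene_count"].to_numpy()
            _write(loads, outdir / f"loads_{cohort}.tsv", manifest)
        dip = test_multimodality(loads_by_cohort, seed=config.seed)
        _write(dip, outdir / "multimodality.tsv", manifest)
        top = top_frequent_genes(freqs, model, n=config.top_n_genes)
        _write(top, outdir / "top_genes.tsv", manifest)

    if "enumerate" in config.stages and matrices:
        for cohort, matrix in matrices.items():
            gpairs = [
                classify_pair(p, model)
                for p in enumerate_gene_pairs(matrix, config.min_freq)
            ]
            pair_lists[cohort] = gpairs
            _write(pairs_to_frame(gpairs), outdir / f"pairs_gene_{cohort}.tsv", manifest)
            ppairs = [
                classify_pair(p, model)
                for p in enumerate_position_pairs(
                    by_cohort[cohort], matrix.n_subjects, config.min_freq)
            ]
            _write(pairs_to_frame(ppairs), outdir / f"pairs_position_{cohort}.tsv", manifest)
        if len(pair_lists) >= 2:
            _write(cross_cohort_sharing(pair_lists), outdir / "sharing.tsv", manifest)

    if "phenotype" in config.stages and matrices:
        cl = clinical.set_index("subject_id")
        for cohort, matrix in matrices.items():
            pairs = pair_lists.get(cohort, [])
            genes_in_pairs = sorted({g for p in pairs for g in (p.entity_a, p.entity_b)})
            for pheno in ("age", "sex", "race"):
                if pheno not in cl.columns:
                    continue
                values = cl[pheno]
                screen = screen_phenotype(matrix, pairs, values, pheno, config.alpha)
                if pheno in ("age", "sex"):
                    singles = screen_single_genes_phenotype(
                        matrix, genes_in_pairs, values, pheno, config.alpha)
                    screen = add_single_comparison(screen, singles, pairs)
                    _write(singles, outdir / f"phenotype_single_{pheno}_{cohort}.tsv", manifest)
                _write(screen, outdir / f"phenotype_{pheno}_{cohort}.tsv", manifest)

    survival_screens = {}
    if "survival" in config.stages and matrices:
        for cohort, matrix in matrices.items():
            pairs = pair_lists.get(cohort, [])
            screen = screen_survival(
                matrix, pairs, clinical, config.min_events, config.alpha,
                config.marginal_upper, config.min_cohort_size,
            )
            genes_in_pairs = sorted({g for p in pairs for g in (p.entity_a, p.entity_b)})
            singles = screen_single_genes(
                matrix, genes_in_pairs, clinical, config.min_events,
                config.alpha, config.marginal_upper,
            )
            sdict = {row["entity"]: row for _, row in singles.iterrows()}
            by_id = {p.pair_id: p for p in pairs}
            if len(screen):
                screen["adds_value_over_singles"] = [
                    comutation_adds_value(
                        row, sdict.get(by_id[row["entity"]].entity_a),
                        sdict.get(by_id[row["entity"]].entity_b))
                    for _, row in screen.iterrows()
                ]
            survival_screens[cohort] = screen
            _write(screen, outdir / f"survival_{cohort}.tsv", manifest)
            _write(singles, outdir / f"survival_single_{cohort}.tsv", manifest)
            bfit = burden_survival(matrix, clinical)
            _write(
                pd.DataFrame([{
                    "entity": "mutational_burden", "hr": bfit.hr,
                    "ci_low": bfit.ci_low, "ci_high": bfit.ci_high,
                    "p": bfit.p, "converged": bfit.converged,
                }]),
                outdir / f"survival_burden_{cohort}.tsv", manifest,
            )

    if "functional" in config.stages:
        if config.motifs and config.reference:
            from Bio import SeqIO

            motifs = load_motifs(config.motifs)
            reference = {
                rec.id: str(rec.seq)
                for rec in SeqIO.parse(config.reference, "fasta")
            }
            strands = {g.gene_id: g.strand for g in model}
            events = scan_mutations(records, reference, motifs, strands)
            _write(events_to_frame(events), outdir / "motif_events.tsv", manifest)
        if config.impact_scores:
            raw = pd.read_csv(config.impact_scores, sep="\t")
            _write(normalize_scores(raw), outdir / "impact_normalized.tsv", manifest)
        if config.panels:
            panels = {
                name: [l.strip() for l in open(p) if l.strip()]
                for name, p in sorted(config.panels.items())
            }
            comut_genes = sorted({
                g for pairs in pair_lists.values() for p in pairs
                for g in (p.entity_a, p.entity_b)
            })
            table, coverage = panel_intersections(panels, comut_genes)
            table = table.copy()
            for k, v in coverage.items():
                table.attrs[k] = v
            _write(table, outdir / "panel_patterns.tsv", manifest)
            with open(outdir / "panel_coverage.json", "w") as fh:
                json.dump(coverage, fh, indent=1, sort_keys=True)
            manifest["outputs"]["panel_coverage.json"] = {
                "rows": len(coverage),
                "sha256": hashlib.sha256(
                    (outdir / "panel_coverage.json").read_bytes()).hexdigest(),
            }

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return outdir
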