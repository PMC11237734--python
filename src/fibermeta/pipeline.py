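"""End-to-end orchestration: per-study diversity and DA, cross-study traits,
phylogenetic conservation, and table-shaped summaries.

A :class:`PipelineConfig` names the per-study inputs and all analysis
parameters; :func:`run_pipeline` executes every stage and returns a report
bundle of plain DataFrames plus a manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (
    CountTable, SampleMetadata, read_count_table, read_metadata, read_newick,
    read_fasta_alignment, ValidationError,
)
from .alpha import alpha_response, METRICS
from .beta import averaged_bray_curtis, permanova_sequential, permdisp
from .diffabund import nb_differential, classify_responders
from .cross_study import filter_otus, prevalence_filter, aggregate_log2fc
from .phylo import (
    pairwise_distance, neighbor_joining, root_with_outgroup, run_conservation,
)

__all__ = ["StudyInput", "PipelineConfig", "run_pipeline",
           "summarize_diversity", "summarize_conservation", "ReportBundle"]

logger = logging.getLogger("fibermeta")


@dataclass
class StudyInput:
    name: str
    counts: str | None = None  # path to count TSV
    metadata: str | None = None  # path to metadata TSV
    table: CountTable | None = None  # in-memory alternative
    meta: SampleMetadata | None = None


@dataclass
class PipelineConfig:
    """Declarative description of one full analysis run.

    Defaults follow the published analysis: 1,000 rarefaction iterations,
    999 PERMANOVA permutations, BH-adjusted p < 0.05 with log2FC cutoffs
    {0, 0.58}, widespreadness over >= 3 studies, consenTRAIT cutoff 0.9.
    """

    studies: list = field(default_factory=list)
    tree: str | None = None  # newick path
    alignment: str | None = None  # aligned FASTA path (NJ built from it)
    outgroup: str | None = None
    rarefaction_depth: int | None = None  # None: per-study minimum total
    n_iter: int = 1000
    n_perm: int = 999
    da_alpha: float = 0.05
    lfc_cut: float = 0.0
    min_total: int = 10
    min_samples: int = 3
    min_fraction: float = 0.5
    min_studies: int = 3
    consentrait_cutoff: float = 0.9
    consentrait_n_perm: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if not self.studies:
            raise ValidationError("config lists no studies")
        if not (0 < self.da_alpha < 1):
            raise ValidationError("da_alpha must be in (0, 1)")
        if not (0.5 < self.consentrait_cutoff <= 1):
            raise ValidationError("consentrait_cutoff must be in (0.5, 1]")
        if not (0 < self.min_fraction <= 1):
            raise ValidationError("min_fraction must be in (0, 1]")
        for s in self.studies:
            for kind in ("counts", "metadata"):
                p = getattr(s, kind)
                if p is None:
                    if (s.table if kind == "counts" else s.meta) is None:
                        raise ValidationError(
                            f"study {s.name!r}: missing {kind}"
                        )
                elif not Path(p).exists():
                    raise ValidationError(
                        f"study {s.name!r}: {kind} path {p} does not exist"
                    )
        for kind in ("tree", "alignment"):
            p = getattr(self, kind)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"{kind} path {p} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        studies = [StudyInput(**s) for s in raw.pop("studies", [])]
        cfg = cls(studies=studies, **raw)
        return cfg


@dataclass
class ReportBundle:
    alpha_summary: pd.DataFrame
    beta_summary: pd.DataFrame
    da_tables: dict
    trait_table: pd.DataFrame | None
    conservation: object | None
    manifest: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.alpha_summary.to_csv(outdir / "alpha_summary.tsv", sep="\t",
                                  index=False, lineterminator="\n")
        self.beta_summary.to_csv(outdir / "beta_summary.tsv", sep="\t",
                                 index=False, lineterminator="\n")
        for name, da in self.da_tables.items():
            da.table.to_csv(outdir / f"da_{name}.tsv", sep="\t",
                            lineterminator="\n")
        if self.trait_table is not None:
            self.trait_table.to_csv(outdir / "trait_assignment.tsv", sep="\t",
                                    lineterminator="\n")
        if self.conservation is not None:
            rep = self.conservation
            pd.DataFrame(
                [{
                    "n_positive_otus": rep.n_positive_otus,
                    "n_negative_otus": rep.n_negative_otus,
                    "positive_tau_d": rep.positive.tau_d,
                    "positive_p": rep.positive.permutation_p,
                    "negative_tau_d": rep.negative.tau_d,
                    "negative_p": rep.negative.permutation_p,
                }]
            ).to_csv(outdir / "conservation.tsv", sep="\t", index=False,
                     lineterminator="\n")
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _load_study(s: StudyInput) -> tuple[CountTable, SampleMetadata]:
    table = s.table if s.table is not None else read_count_table(s.counts)
    meta = s.meta if s.meta is not None else read_metadata(s.metadata)
    missing = set(table.sample_ids) - set(meta.sample_ids)
    if missing:
        raise ValidationError(
            f"study {s.name!r}: samples without metadata: {sorted(missing)[:5]}"
        )
    return table, meta


def _stage(name: str, study: str | None = None):
    tag = f"{name}[{study}]" if study else name
    t0 = time.perf_counter()

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, et, ev, tb):
            if et is not None:
                logger.error("stage %s failed: %s", tag, ev)
                raise ValidationError(f"stage {tag} failed: {ev}") from ev
            logger.info("stage %s done in %.2fs", tag, time.perf_counter() - t0)
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run the whole per-study and cross-study analysis.

    Per study: alpha response (direction + significance per metric),
    averaged Bray-Curtis PERMANOVA (subject %, fiber %, significance) with
    a dispersion check, and the differential-abundance table on filtered
    counts. Across studies: widespread-OTU trait aggregation and the
    paired consenTRAIT conservation report (requires a tree or alignment).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    seeds = {k: int(rng.integers(2 ** 31)) for k in
             ("alpha", "beta", "perma", "disp", "cons")}

    alpha_rows = []
    beta_rows = []
    da_tables = {}
    presence = {}
    for s_idx, s in enumerate(config.studies):
        with _stage("load", s.name):
            table, meta = _load_study(s)
        logger.info("study %s: %d OTUs x %d samples", s.name, *table.shape)
        depth = config.rarefaction_depth or int(table.sample_totals().min())

        with _stage("alpha", s.name):
            ares = alpha_response(
                table, meta, depth=depth, n_iter=config.n_iter,
                seed=[seeds["alpha"], s_idx],
            )
        row = {"study": s.name, "n_samples": table.shape[1],
               "n_subjects": len(meta.paired_subjects()),
               "rarefaction_depth": ares.depth}
        for m in METRICS:
            t = ares.tests[m]
            row[f"{m}_direction"] = t.direction
            row[f"{m}_p"] = t.p
            row[f"{m}_percent_change"] = t.percent_change
        alpha_rows.append(row)

        with _stage("beta", s.name):
            dm = averaged_bray_curtis(
                table, depth, n_iter=config.n_iter,
                seed=[seeds["beta"], s_idx],
            )
            meta_kept = meta.subset(dm.ids)
            perma = permanova_sequential(
                dm, meta_kept, terms=("subject_id", "timepoint"),
                n_perm=config.n_perm, seed=[seeds["perma"], s_idx],
            )
            disp = permdisp(
                dm, meta_kept.timepoint_of(), n_perm=config.n_perm,
                seed=[seeds["disp"], s_idx],
            )
        subj = perma.term("subject_id")
        fib = perma.term("timepoint")
        beta_rows.append({
            "study": s.name,
            "subject_pct": 100.0 * subj.r2, "subject_p": subj.p,
            "fiber_pct": 100.0 * fib.r2, "fiber_p": fib.p,
            "dispersion_f": disp.f, "dispersion_p": disp.p,
        })

        with _stage("da", s.name):
            filt = filter_otus(table, config.min_total, config.min_samples)
            prev = prevalence_filter(filt, config.min_fraction)
            da = nb_differential(prev, meta, pseudo_reference=True)
        da_tables[s.name] = da
        presence[s.name] = set(prev.otu_ids)

    trait_table = None
    traits = None
    if len(config.studies) >= config.min_studies:
        with _stage("aggregate"):
            traits = aggregate_log2fc(da_tables, presence,
                                      min_studies=config.min_studies)
        trait_table = traits.table

    conservation = None
    if traits is not None and (config.tree or config.alignment):
        with _stage("conservation"):
            if config.tree:
                tree = read_newick(config.tree)
            else:
                aln = read_fasta_alignment(config.alignment)
                dm = pairwise_distance(aln)
                tree = neighbor_joining(dm)
                if config.outgroup:
                    tree = root_with_outgroup(tree, config.outgroup)
            conservation = run_conservation(
                tree, traits, n_perm=config.consentrait_n_perm,
                seed=seeds["cons"], cutoff=config.consentrait_cutoff,
                outgroup=config.outgroup,
            )

    manifest = {
        "fibermeta_version": __version__,
        "seed": config.seed,
        "derived_seeds": seeds,
        "parameters": {
            k: v for k, v in asdict(config).items() if k != "studies"
        },
        "studies": [s.name for s in config.studies],
    }
    return ReportBundle(
        alpha_summary=pd.DataFrame(alpha_rows),
        beta_summary=pd.DataFrame(beta_rows),
        da_tables=da_tables,
        trait_table=trait_table,
        conservation=conservation,
        manifest=manifest,
    )


def summarize_diversity(alpha_summary: pd.DataFrame, beta_summary: pd.DataFrame,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Per-study diversity summary with average and significant-only rows.

    Mirrors the shape of the published per-intervention summary: one row
    per study with alpha-metric directions/significance and the subject and
    fiber variance percentages, then an unconditional average row and an
    average over studies whose fiber term is significant.
    """
    df = alpha_summary.merge(beta_summary, on="study")
    rows = []
    for _, r in df.iterrows():
        row = {"study": r["study"]}
        for m in METRICS:
            sig = "significant" if r[f"{m}_p"] < alpha else "n.s."
            arrow = {"increase": "up", "decrease": "down", "none": "-"}[
                r[f"{m}_direction"]]
            row[m] = f"{arrow} {sig}"
        row["subject_pct"] = r["subject_pct"]
        row["fiber_pct"] = r["fiber_pct"]
        row["fiber_significant"] = bool(r["fiber_p"] < alpha)
        rows.append(row)
    out = pd.DataFrame(rows)
    avg = {"study": "Average",
           "subject_pct": out["subject_pct"].mean(),
           "fiber_pct": out["fiber_pct"].mean()}
    sig = out[out["fiber_significant"]]
    avg_sig = {
        "study": "Average - significant only",
        "subject_pct": sig["subject_pct"].mean() if len(sig) else float("nan"),
        "fiber_pct": sig["fiber_pct"].mean() if len(sig) else float("nan"),
    }
    return pd.concat([out, pd.DataFrame([avg, avg_sig])], ignore_index=True)


def summarize_conservation(reports: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Per-study conservation summary with average and significant-only rows.

    ``reports`` maps study (or run) name -> ConservationReport. Averages
    of positive and negative tau_D are taken over all rows, and over the
    rows where the respective permutation test is significant.
    """
    rows = []
    for name, rep in reports.items():
        rows.append({
            "study": name,
            "positive_otus": rep.n_positive_otus,
            "negative_otus": rep.n_negative_otus,
            "positive_tau_d": rep.positive.tau_d,
            "positive_p": rep.positive.permutation_p,
            "negative_tau_d": rep.negative.tau_d,
            "negative_p": rep.negative.permutation_p,
        })
    out = pd.DataFrame(rows)
    avg = {"study": "Average",
           "positive_tau_d": out["positive_tau_d"].mean(),
           "negative_tau_d": out["negative_tau_d"].mean()}
    pos_sig = out[out["positive_p"] < alpha]
    neg_sig = out[out["negative_p"] < alpha]
    avg_sig = {
        "study": "Average - significant only",
        "positive_tau_d": pos_sig["positive_tau_d"].mean()
        if len(pos_sig) else float("nan"),
        "negative_tau_d": neg_sig["negative_tau_d"].mean()
        if len(neg_sig) else float("nan"),
    }
    return pd.concat([out, pd.DataFrame([avg, avg_sig])], ignore_index=True)
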