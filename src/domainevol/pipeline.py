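"""End-to-end pipeline: filter -> tree -> conservation -> dN/dS -> NLS -> pI.

A single JSON config drives the run; every stage is also independently
invocable through its module (or the command line).  A manifest ties
each output to the inputs, parameters and seed that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .conservation import (
    DomainPartition,
    conservation_profile,
    domain_summary,
    group_vs_modal,
    heatmap_table,
)
from .contrasts import fit_factorial, lsmeans_contrasts
from .dnds import group_domain_dnds
from .filtering import complete_deletion, modal_gap_deletion
from .nls import classify_alignment, classify_sequence
from .phylo import bootstrap_supports, jtt_model
from .physchem import isoelectric_point
from .seqio import Alignment, read_fasta, read_metadata, write_fasta, write_newick

logger = logging.getLogger(__name__)

DEFAULT_STAGES = ("filter", "tree", "conserve", "dnds", "nls", "pi")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> Path:
    """Run the configured stages; returns the report directory.

    Config keys: ``protein_fasta`` (required), ``codon_fasta``,
    ``metadata``, ``partition`` (paths); ``stages`` (default all
    applicable); ``groups`` (focal/reference group names for the
    clade-vs-modal contrast); ``bootstrap`` {reps, seed, collapse};
    ``contrast_table`` (long-format TSV for the stats stage).
    """
    if not isinstance(config, dict):
        config = json.loads(Path(config).read_text())
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = tuple(config.get("stages", DEFAULT_STAGES))
    manifest: dict = {
        "version": __version__,
        "config": config,
        "stages": {},
        "outputs": {},
    }
    t_start = time.time()

    def _run(stage, fn):
        t0 = time.time()
        try:
            fn()
        except Exception as exc:
            logger.error("stage %s failed after %.1fs", stage, time.time() - t0)
            raise PipelineError(stage, exc) from exc
        manifest["stages"][stage] = round(time.time() - t0, 3)
        logger.info("stage %s done in %.1fs", stage, manifest["stages"][stage])

    def _record(name: str, path: Path):
        manifest["outputs"][name] = {"path": path.name, "sha256": _sha256(path)}

    aln = read_fasta(config["protein_fasta"])
    codon_aln = read_fasta(config["codon_fasta"]) if config.get("codon_fasta") else None
    meta = read_metadata(config["metadata"]) if config.get("metadata") else None
    if meta is not None:
        meta.resolve(aln)
    partition: Optional[DomainPartition] = (
        DomainPartition.from_json(config["partition"])
        if config.get("partition")
        else None
    )

    state: dict = {}

    if "filter" in stages:
        def stage_filter():
            comp = complete_deletion(aln)
            modal = modal_gap_deletion(aln)
            state["complete"] = comp.alignment
            state["modal"] = modal.alignment
            p1 = outdir / "filtered_complete.fasta"
            p2 = outdir / "filtered_modal.fasta"
            write_fasta(comp.alignment, p1)
            write_fasta(modal.alignment, p2)
            (outdir / "retained_complete.tsv").write_text(comp.retained_tsv())
            (outdir / "retained_modal.tsv").write_text(modal.retained_tsv())
            _record("filtered_complete", p1)
            _record("filtered_modal", p2)
        _run("filter", stage_filter)

    if "tree" in stages:
        def stage_tree():
            boot = config.get("bootstrap", {})
            tree = bootstrap_supports(
                state.get("complete", complete_deletion(aln).alignment),
                n_reps=int(boot.get("reps", 100)),
                seed=int(boot.get("seed", 0)),
                model=jtt_model(),
                collapse_below=int(boot.get("collapse", 50)),
            )
            p = outdir / "tree.nwk"
            write_newick(tree, p)
            _record("tree", p)
        _run("tree", stage_tree)

    if "conserve" in stages:
        def stage_conserve():
            if partition is None:
                raise ValueError("conserve stage requires a partition config")
            profile = conservation_profile(aln, reference=partition.reference)
            state["profile"] = profile
            p1 = outdir / "conservation_profile.tsv"
            heatmap_table(profile, partition).to_csv(p1, sep="\t", index=False)
            p2 = outdir / "conservation_domains.tsv"
            domain_summary(profile, partition).to_csv(p2, sep="\t", index=False)
            _record("conservation_profile", p1)
            _record("conservation_domains", p2)
            if meta is not None and config.get("groups"):
                focal_g, ref_g = config["groups"]["focal"], config["groups"]["reference"]
                gvm = group_vs_modal(
                    aln,
                    [i for i in meta.ids_in_group(focal_g) if i in aln],
                    [i for i in meta.ids_in_group(ref_g) if i in aln],
                    partition,
                )
                p3 = outdir / "group_vs_modal.tsv"
                gvm.to_csv(p3, sep="\t", index=False)
                _record("group_vs_modal", p3)
        _run("conserve", stage_conserve)

    if "dnds" in stages:
        def stage_dnds():
            if codon_aln is None:
                raise ValueError("dnds stage requires codon_fasta in the config")
            if partition is None:
                raise ValueError("dnds stage requires a partition config")
            groups = (
                sorted({e.group for e in meta.entries.values()})
                if meta is not None
                else [None]
            )
            rows = []
            for group in groups:
                ids = meta.ids_in_group(group) if group else codon_aln.ids
                if len(ids) < 2:
                    continue
                for domain, res in group_domain_dnds(
                    codon_aln, partition, ids
                ).items():
                    rows.append({"group": group or "all", "domain": domain,
                                 **res.as_dict()})
            p = outdir / "dnds.tsv"
            pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
            _record("dnds", p)
        _run("dnds", stage_dnds)

    if "nls" in stages:
        def stage_nls():
            rows = []
            if partition is not None and "NLS" in partition.intervals:
                calls = classify_alignment(aln, partition)
                for rec_id, (functional, best) in calls.items():
                    rows.append(
                        {"id": rec_id, "functional": functional, "best_score": best}
                    )
            else:
                for rec in aln.records:
                    functional, best, cands = classify_sequence(rec.ungapped)
                    rows.append(
                        {"id": rec.id, "functional": functional, "best_score": best}
                    )
            p = outdir / "nls.tsv"
            pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
            _record("nls", p)
        _run("nls", stage_nls)

    if "pi" in stages:
        def stage_pi():
            if partition is None:
                raise ValueError("pi stage requires a partition config")
            ref = aln.get(partition.reference).ungapped
            rows = []
            for name, (lo, hi) in partition.intervals.items():
                segment = ref[lo - 1 : hi]
                rows.append(
                    {
                        "domain": name,
                        "pI": round(isoelectric_point(segment), 2),
                        "length": len(segment),
                    }
                )
            p = outdir / "isoelectric_points.tsv"
            pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
            _record("isoelectric_points", p)
        _run("pi", stage_pi)

    if "stats" in stages:
        def stage_stats():
            table = config.get("contrast_table")
            if table is None:
                raise ValueError("stats stage requires contrast_table in the config")
            data = pd.read_csv(table, sep="\t")
            fit = fit_factorial(data)
            out = []
            for family in ("within-protein", "within-domain"):
                t = lsmeans_contrasts(fit, family)
                t.insert(0, "family", family)
                out.append(t)
            p = outdir / "contrasts.tsv"
            pd.concat(out).to_csv(p, sep="\t", index=False)
            p2 = outdir / "term_tests.tsv"
            fit.term_tests.to_csv(p2, sep="\t")
            _record("contrasts", p)
            _record("term_tests", p2)
        _run("stats", stage_stats)

    manifest["elapsed"] = round(time.time() - t_start, 3)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return outdir
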