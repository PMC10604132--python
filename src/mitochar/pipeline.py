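"""End-to-end orchestration of the analysis stages.

Stages: composition -> codon usage -> architecture -> control-region
blocks / hairpin -> phylogeny -> selection. Each stage writes a TSV (or
newick) into the output directory; a stage failure is recorded and later
independent stages still run. The whole bundle is a pure function of
(inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import traceback
from pathlib import Path

import pandas as pd

from . import __version__
from .architecture import find_overlaps, find_spacers, gene_order, locate_control_region
from .codon_usage import (
    classify_start_stop,
    genome_codon_counts,
    rscu,
    split_codons,
    usage_table,
)
from .composition import region_report
from .genome_io import MitoGenome, extract_feature_sequence, feature_length
from .msa import concatenate, progressive_align
from .noncoding import block_composition_table, detect_csbs, find_stem_loops, hairpin_table
from .phylogeny import bootstrap_support
from .selection import CodonAlignment, classify_summary, fel_lite, slac

log = logging.getLogger("mitochar")


@dataclasses.dataclass
class RunConfig:
    out_dir: str = "mitochar_out"
    code_id: int = 2
    seed: int = 0
    boot_reps: int = 100
    phylo_model: str = "JC69"
    alpha: float = 0.05
    csb_window: int = 15
    csb_min_identity: float = 0.85
    csb_min_block: int = 12
    csb_max_gap_frac: float = 0.2
    hairpin_min_stem: int = 5
    selection_method: str = "slac"
    stages: tuple[str, ...] = (
        "summary",
        "composition",
        "codons",
        "architecture",
        "csb",
        "hairpin",
        "phylo",
        "selection",
    )


def general_features_table(genomes: list[MitoGenome]) -> pd.DataFrame:
    rows = []
    for g in genomes:
        pcgs = g.features_of("PCG")
        trnas = g.features_of("tRNA")
        rrnas = g.features_of("rRNA")
        starts = stops = ""
        if g.sequence is not None and pcgs:
            cls = [
                classify_start_stop(
                    split_codons(extract_feature_sequence(g, f), gene=f.name)
                )
                for f in pcgs
            ]
            starts = ";".join(f"{f.name}:{c[0]}" for f, c in zip(pcgs, cls))
            stops = ";".join(f"{f.name}:{c[1]}" for f, c in zip(pcgs, cls))
        rows.append(
            {
                "genome": g.id,
                "length_bp": g.length,
                "n_features": len(g.features),
                "n_PCG": len(pcgs),
                "n_tRNA": len(trnas),
                "n_rRNA": len(rrnas),
                "n_L_strand_tRNA": sum(1 for f in trnas if f.strand == "L"),
                "PCG_total_bp": sum(
                    feature_length(f, g.length, g.circular) for f in pcgs
                ),
                "start_classes": starts,
                "stop_classes": stops,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(genomes: list[MitoGenome], cfg: RunConfig) -> dict:
    """Run all configured stages; returns {stage: output path or error}."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    log.info("mitochar %s; config: %s", __version__, dataclasses.asdict(cfg))
    (out / "run_config.json").write_text(
        json.dumps(
            {"version": __version__, "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
             **dataclasses.asdict(cfg)},
            indent=2, default=str,
        )
    )
    status: dict[str, str] = {}
    with_seq = [g for g in genomes if g.sequence is not None]

    def stage(name, fn):
        if name not in cfg.stages:
            return
        try:
            fn()
            status[name] = "ok"
        except Exception as e:  # noqa: BLE001 - recorded, later stages run
            log.error("stage %s failed: %s", name, e)
            log.debug(traceback.format_exc())
            status[name] = f"failed: {e}"

    def do_summary():
        general_features_table(genomes).to_csv(
            out / "general_features.tsv", sep="\t", index=False
        )

    def do_composition():
        if not with_seq:
            raise ValueError("no genome has a sequence; stage skipped")
        frames = []
        for g in with_seq:
            df = region_report(g)
            df.insert(0, "genome", g.id)
            frames.append(df)
        pd.concat(frames).to_csv(out / "composition.tsv", sep="\t", index=False)

    def do_codons():
        if not with_seq:
            raise ValueError("no genome has a sequence; stage skipped")
        frames = []
        for g in with_seq:
            t = rscu(genome_codon_counts(g, code_id=cfg.code_id))
            df = usage_table(t)
            df.insert(0, "genome", g.id)
            frames.append(df)
        pd.concat(frames).to_csv(out / "codon_usage.tsv", sep="\t", index=False)

    def do_architecture():
        rows = []
        arr_rows = []
        for g in genomes:
            for r in find_overlaps(g):
                rows.append({"genome": g.id, "kind": "overlap", "a": r.gene_a,
                             "b": r.gene_b, "length": r.length,
                             "motif": r.motif or ""})
            for r in find_spacers(g):
                rows.append({"genome": g.id, "kind": "spacer", "a": r.gene_a,
                             "b": r.gene_b, "length": r.length, "motif": ""})
            arr_rows.append({
                "genome": g.id,
                "arrangement": " ".join(
                    ("" if s == "H" else "-") + n for n, s in gene_order(g)
                ),
            })
        pd.DataFrame(rows).to_csv(out / "architecture.tsv", sep="\t", index=False)
        pd.DataFrame(arr_rows).to_csv(out / "arrangement.tsv", sep="\t",
                                      index=False)

    def _cr_seqs():
        seqs = {}
        for g in with_seq:
            cr = locate_control_region(g)
            s, e = cr.start, cr.end
            seqs[g.id] = (
                g.sequence[s - 1 : e] if e >= s
                else g.sequence[s - 1 :] + g.sequence[:e]
            )
        return seqs

    def do_csb():
        seqs = _cr_seqs()
        if len(seqs) < 3:
            raise ValueError("CSB stage needs >= 3 genomes with sequence")
        if len({len(s) for s in seqs.values()}) == 1:
            taxa = sorted(seqs)
            rows = [seqs[t] for t in taxa]
        else:
            aln = progressive_align(seqs)
            taxa, rows = aln.taxa, aln.rows
        blocks = detect_csbs(
            rows,
            window=cfg.csb_window,
            min_identity=cfg.csb_min_identity,
            min_block=cfg.csb_min_block,
            max_gap_frac=cfg.csb_max_gap_frac,
        )
        df = block_composition_table(blocks)
        df["aln_start"] = [b.aln_start for b in blocks]
        df["aln_end"] = [b.aln_end for b in blocks]
        df["mean_identity"] = [b.mean_identity for b in blocks]
        df.to_csv(out / "csb.tsv", sep="\t", index=False)

    def do_hairpin():
        rows = []
        for g in with_seq:
            trnn = g.feature("trnN")
            trnc = g.feature("trnC")
            region = g.sequence[trnn.end : trnc.start - 1]
            hps = find_stem_loops(region, min_stem=cfg.hairpin_min_stem)
            if hps:
                df = hairpin_table(hps[:1])
                df.insert(0, "genome", g.id)
                rows.append(df)
        if not rows:
            raise ValueError("no hairpin candidates found")
        pd.concat(rows).to_csv(out / "hairpin.tsv", sep="\t", index=False)

    phylo_result: dict = {}

    def do_phylo():
        if len(with_seq) < 4:
            raise ValueError("phylogeny needs >= 4 genomes with sequence")
        gene_alns = _per_gene_alignments(with_seq)
        supermatrix = concatenate(gene_alns)
        tree = bootstrap_support(
            supermatrix, model=cfg.phylo_model, n_reps=cfg.boot_reps,
            seed=cfg.seed,
        )
        (out / "supermatrix_partitions.txt").write_text(
            "".join(f"{g} = {s}-{e}\n" for g, s, e in supermatrix.partition)
        )
        (out / "tree.nwk").write_text(tree.newick() + "\n")
        phylo_result["tree"] = tree
        phylo_result["gene_alns"] = gene_alns

    def do_selection():
        if "tree" not in phylo_result:
            raise ValueError("selection requires the phylogeny stage")
        tree = phylo_result["tree"]
        gene_alns = phylo_result["gene_alns"]
        all_results = []
        site_genes = []
        for gene, aln in gene_alns:
            ncol = aln.ncol - aln.ncol % 3
            rows = [r[:ncol] for r in aln.rows]
            try:
                caln = CodonAlignment.from_nucleotide(aln.taxa, rows,
                                                      code_id=cfg.code_id)
            except ValueError as e:
                log.warning("selection: %s skipped (%s)", gene, e)
                continue
            res = slac(caln, tree, alpha=cfg.alpha, code_id=cfg.code_id)
            all_results.extend(res)
            site_genes.extend([gene] * len(res))
        counts, per_gene = classify_summary(all_results, alpha=cfg.alpha,
                                            site_genes=site_genes)
        pd.DataFrame(
            [
                {
                    "gene": g_, "site": r.site, "ES": r.ES, "EN": r.EN,
                    "OS": r.OS, "ON": r.ON, "dN": r.dN, "dS": r.dS,
                    "dN_minus_dS": r.dn_minus_ds, "p": r.p_value,
                    "class": r.classification,
                }
                for g_, r in zip(site_genes, all_results)
            ]
        ).to_csv(out / "selection_sites.tsv", sep="\t", index=False)
        per_gene.to_csv(out / "selection_per_gene.tsv", sep="\t", index=False)
        (out / "selection_summary.json").write_text(json.dumps(counts, indent=2))

    stage("summary", do_summary)
    stage("composition", do_composition)
    stage("codons", do_codons)
    stage("architecture", do_architecture)
    stage("csb", do_csb)
    stage("hairpin", do_hairpin)
    stage("phylo", do_phylo)
    stage("selection", do_selection)
    (out / "stage_status.json").write_text(json.dumps(status, indent=2))
    return status


def _per_gene_alignments(genomes: list[MitoGenome]):
    """13-PCG per-gene alignments (direct when lengths agree, progressive
    otherwise), sense strands."""
    gene_names = sorted(
        set.intersection(
            *({f.name for f in g.features_of("PCG")} for g in genomes)
        )
    )
    from .msa import Alignment

    out = []
    for gene in gene_names:
        seqs = {
            g.id: extract_feature_sequence(g, g.feature(gene)) for g in genomes
        }
        if len({len(s) for s in seqs.values()}) == 1:
            taxa = sorted(seqs)
            aln = Alignment(taxa=taxa, rows=[seqs[t] for t in taxa])
        else:
            aln = progressive_align(seqs)
        out.append((gene, aln))
    return out
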