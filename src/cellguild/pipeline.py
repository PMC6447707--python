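"""End-to-end orchestration: simulate -> classify-16s -> annotate -> bin
-> roles -> protprops -> report.

One master seed fans out to per-stage sub-seeds through a stage-name
hash, so disabling a stage never shifts the randomness of the others,
and a manifest records every parameter needed to reproduce a run.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, references as refs
from . import amplicon as amp
from . import annotate as ann
from . import binning as bng
from . import io as cio
from . import protprops as pp
from . import roles as rl
from . import synth
from .taxonomy import default_taxonomy


def stage_seed(master: int, stage: str) -> int:
    return (zlib.crc32(stage.encode()) ^ int(master)) % 2**31


@dataclass
class PipelineConfig:
    """All stage parameters; defaults follow the published analysis values
    where one exists (overlap 50, min length 300, EE 0.5, confidence 0.5,
    bootstrap 100, contig minimum 1000, k 5, 50 intermediate dimensions,
    perplexity 30.0, theta 0.5, seed 0)."""

    seed: int = 0
    outdir: str = "results/pipeline"
    # synth
    n_samples: int = 2
    genome_length: int = 30_000
    lognormal_sigma: float = 1.0
    contigs_per_genome: int = 150
    amplicon_pairs: int = 200
    read_length: int = 250
    error_rate: float = 0.005
    cassette_identity: float = 0.80
    # amplicon
    min_overlap: int = 50
    min_length: int = 300
    max_expected_error: float = 0.5
    min_q: float = 30.0
    confidence_threshold: float = 0.5
    n_bootstrap: int = 100
    # annotate
    min_protein_length: int = 100
    min_contig_length: int = 300
    # binning
    bin_min_length: int = 1000
    kmer: int = 5
    intermediate_dims: int = 50
    perplexity: float = 30.0
    theta: float = 0.5
    # stage switches
    stages: tuple[str, ...] = (
        "simulate", "classify-16s", "annotate", "bin", "roles", "protprops",
        "report",
    )


@dataclass
class PipelineState:
    genomes: list = field(default_factory=list)
    profiles: list = field(default_factory=list)
    contig_sets: list = field(default_factory=list)
    amplicons: dict = field(default_factory=dict)   # sample -> (pairs, truth)
    assignments: dict = field(default_factory=dict)
    abundance: pd.DataFrame | None = None
    annotations: pd.DataFrame | None = None
    hits: list = field(default_factory=list)
    bins: list = field(default_factory=list)
    noise: list = field(default_factory=list)
    coords: pd.DataFrame | None = None
    role_calls: list = field(default_factory=list)
    metrics: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all enabled stages in order; returns the report directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    state = PipelineState()
    order = ["simulate", "classify-16s", "annotate", "bin", "roles",
             "protprops", "report"]
    runners = {
        "simulate": _stage_simulate,
        "classify-16s": _stage_classify,
        "annotate": _stage_annotate,
        "bin": _stage_bin,
        "roles": _stage_roles,
        "protprops": _stage_protprops,
        "report": _stage_report,
    }
    for stage in order:
        if stage not in config.stages:
            continue
        try:
            runners[stage](config, state, out)
        except Exception as exc:  # noqa: BLE001 - name the failing stage
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": asdict(config),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


# ---------------------------------------------------------------------------
# stages

def _stage_simulate(cfg: PipelineConfig, st: PipelineState, out: Path) -> None:
    seed = stage_seed(cfg.seed, "simulate")
    st.genomes, st.profiles = synth.simulate_default_community(
        seed=seed, n_samples=cfg.n_samples, sigma=cfg.lognormal_sigma,
        length=cfg.genome_length,
    )
    rng = np.random.default_rng(seed + 1)
    for profile in st.profiles:
        cs = synth.shear_contigs_per_genome(
            st.genomes, cfg.contigs_per_genome,
            seed=int(rng.integers(2**31)), prefix=f"{profile.sample}_c",
        )
        st.contig_sets.append(cs)
        pairs, truth = synth.simulate_amplicons(
            st.genomes, profile, read_length=cfg.read_length,
            error_rate=cfg.error_rate, n_pairs=cfg.amplicon_pairs,
            seed=int(rng.integers(2**31)),
        )
        st.amplicons[profile.sample] = (pairs, truth)
    cio.write_fasta({g.id: g.sequence for g in st.genomes}, out / "genomes.fasta")
    for profile, cs in zip(st.profiles, st.contig_sets):
        cio.write_fasta({c.id: c.sequence for c in cs.contigs},
                        out / f"contigs_{profile.sample}.fasta")
        gm = {g.id: g for g in st.genomes}
        cio.write_tsv(cs.truth(gm), out / f"contig_truth_{profile.sample}.tsv")
        pairs, truth = st.amplicons[profile.sample]
        cio.write_fastq([p[0] for p in pairs], out / f"reads_{profile.sample}_R1.fastq")
        cio.write_fastq([p[1] for p in pairs], out / f"reads_{profile.sample}_R2.fastq")
        cio.write_tsv(truth, out / f"read_truth_{profile.sample}.tsv")
    ab = pd.DataFrame({p.sample: p.abundances for p in st.profiles}).T
    cio.write_tsv(ab.reset_index(names="sample"), out / "community_profiles.tsv")


def _stage_classify(cfg: PipelineConfig, st: PipelineState, out: Path) -> None:
    seed = stage_seed(cfg.seed, "classify-16s")
    tree = default_taxonomy()
    model = amp.train_word_model(synth.make_16s_reference(seed=stage_seed(cfg.seed, "ref16s")), tree)
    per_sample: dict[str, list[amp.TaxonAssignment]] = {}
    truth_all = []
    for sample, (pairs, truth) in sorted(st.amplicons.items()):
        merged = []
        for f, r in pairs:
            m = amp.merge_pairs(f, r, min_overlap=cfg.min_overlap)
            if m is not None:
                merged.append(m)
        kept, _rej = amp.filter_sequences(
            merged, cfg.min_length, cfg.max_expected_error, cfg.min_q
        )
        rng = np.random.default_rng(seed)
        asgns = []
        for read in kept:
            conf = amp.classify_with_bootstrap(
                model, read.bases, cfg.n_bootstrap, seed=int(rng.integers(2**31))
            )
            asgns.append(amp.escalate_assignment(conf, cfg.confidence_threshold,
                                                 read_id=read.id))
        per_sample[sample] = asgns
        truth_all.append(truth)
    st.assignments = per_sample
    raw, filtered = amp.build_abundance_table(per_sample)
    st.abundance = filtered
    cio.write_tsv(raw.reset_index(names="sample"), out / "abundance_raw.tsv")
    cio.write_tsv(filtered.reset_index(names="sample"), out / "abundance_filtered.tsv")
    truth = pd.concat(truth_all, ignore_index=True)
    genus_truth = dict(zip(truth["read"], truth["genus"]))
    correct = total = 0
    for sample, asgns in per_sample.items():
        for a in asgns:
            t = genus_truth.get(a.id)
            if t is None:
                continue
            total += 1
            if a.accepted_rank == "genus" and a.display_name == t:
                correct += 1
    st.metrics["amplicon_genus_accuracy"] = correct / total if total else 0.0
    if filtered.shape[1] >= 2:
        coords, var = amp.pca(filtered)
        cio.write_tsv(coords.reset_index(names="sample"), out / "pca_coords.tsv")
        st.metrics["pca_variance"] = [float(v) for v in var]


def _stage_annotate(cfg: PipelineConfig, st: PipelineState, out: Path) -> None:
    reference = refs.get_references()
    contigs = [c for cs in st.contig_sets for c in cs.contigs]
    genes, hits, table = ann.annotate_contigs(
        contigs, reference, cfg.min_protein_length, cfg.min_contig_length
    )
    st.annotations = table
    st.hits = hits
    cio.write_tsv(table, out / "annotations.tsv")
    if hits:
        cio.write_tsv(ann.genus_identity_stats(hits), out / "genus_identity.tsv")
    # GH-family sets per sample plus the cellulase family set
    per_sample_fams: list[set[str]] = []
    for cs in st.contig_sets:
        ids = {c.id for c in cs.contigs}
        fams: set[str] = set()
        sub = table[table["contig"].isin(ids)]
        for v in sub["gh_families"]:
            fams.update(x for x in str(v).split(",") if x)
        per_sample_fams.append(fams)
    if len(per_sample_fams) >= 2:
        venn = ann.gh_family_venn(per_sample_fams[0], per_sample_fams[1],
                                  set(ann.cellulase_families()))
        cio.write_tsv(pd.DataFrame([venn]), out / "gh_family_venn.tsv")


def _stage_bin(cfg: PipelineConfig, st: PipelineState, out: Path) -> None:
    contigs = [c for cs in st.contig_sets for c in cs.contigs]
    sigs = bng.signatures_for(contigs, k=cfg.kmer, min_length=cfg.bin_min_length)
    coords = bng.embed(sigs, cfg.intermediate_dims, cfg.perplexity, cfg.theta,
                       seed=stage_seed(cfg.seed, "bin"))
    bins, noise = bng.cluster_embedding(coords)
    if st.annotations is not None:
        embedded = st.annotations[st.annotations["contig"].isin(coords.index)]
        bng.overlay_annotations(bins, embedded, set(coords.index))
    st.bins, st.noise, st.coords = bins, noise, coords
    cio.write_tsv(coords.reset_index(names="contig"), out / "bin_coordinates.tsv")
    members = pd.DataFrame(
        [{"contig": c, "bin": b.id} for b in bins for c in b.members]
        + [{"contig": c, "bin": "noise"} for c in noise]
    )
    cio.write_tsv(members, out / "bin_membership.tsv")
    gm = {g.id: g for g in st.genomes}
    truth = pd.concat([cs.truth(gm) for cs in st.contig_sets], ignore_index=True)
    truth = truth[truth["contig"].isin(coords.index)]
    purity, completeness = bng.bin_quality(bins, truth)
    cio.write_tsv(purity, out / "bin_purity.tsv")
    cio.write_tsv(completeness, out / "bin_completeness.tsv")
    st.metrics["median_bin_purity"] = (
        float(purity["purity"].median()) if len(purity) else 0.0
    )
    st.metrics["completeness_ge_075"] = int((completeness["completeness"] >= 0.75).sum())


def _stage_roles(cfg: PipelineConfig, st: PipelineState, out: Path) -> None:
    if st.annotations is None:
        raise RuntimeError("roles stage requires annotations")
    matrix = rl.build_gene_content_matrix(st.annotations, grouping="genus")
    calls = rl.classify_roles(matrix)
    st.role_calls = calls
    cio.write_tsv(matrix.reset_index(names="taxon"), out / "gene_content_matrix.tsv")
    cio.write_tsv(
        pd.DataFrame([{
            "taxon": a.taxon, "role": a.role,
            "transporter_status": a.transporter_status,
            "evidence": ",".join(a.evidence),
        } for a in calls]),
        out / "role_assignments.tsv",
    )
    net = rl.build_network(calls)
    cio.write_tsv(rl.network_edge_list(net), out / "interaction_network.tsv")
    truth = {g.genus: g.role for g in st.genomes}
    known = [a for a in calls if a.taxon in truth]
    if known:
        cm, acc = rl.role_recovery(known, truth)
        cio.write_tsv(cm.reset_index(names="truth"), out / "role_confusion.tsv")
        st.metrics["role_accuracy"] = acc


def _stage_protprops(cfg: PipelineConfig, st: PipelineState, out: Path) -> None:
    reference = refs.get_references()
    proteins = {f"{label}_reference": seq
                for label, seq in sorted(reference.marker_bases.items())}
    table = pp.properties_table(proteins, pH=9.0)
    cio.write_tsv(table, out / "protein_properties.tsv")


def _stage_report(cfg: PipelineConfig, st: PipelineState, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if st.abundance is not None and len(st.abundance):
        fig, ax = plt.subplots(figsize=(7, 4))
        st.abundance.plot.bar(stacked=True, ax=ax, legend=False)
        ax.set_ylabel("relative abundance")
        fig.tight_layout()
        fig.savefig(out / "abundance_barplot.png", dpi=120)
        plt.close(fig)
    if st.coords is not None:
        fig, ax = plt.subplots(figsize=(6, 6))
        ax.scatter(st.coords["x"], st.coords["y"], s=4, c="0.6", label="contigs")
        if st.annotations is not None:
            endo = st.annotations[
                st.annotations["ec_labels"].str.contains("EC:3.2.1.4", na=False)
            ]["contig"].unique()
            sel = st.coords.index.isin(endo)
            ax.scatter(st.coords.loc[sel, "x"], st.coords.loc[sel, "y"],
                       marker="*", s=90, c="darkred", label="endoglucanase")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "binning_scatter.png", dpi=120)
        plt.close(fig)
    (out / "metrics.json").write_text(json.dumps(st.metrics, indent=2))


# ---------------------------------------------------------------------------
# seeded end-to-end benchmark

def end_to_end_metrics(seed: int, contigs_per_genome: int = 150,
                       amplicon_pairs: int = 200, n_samples: int = 2) -> dict:
    """Run the full analysis in memory on one seeded synthetic community.

    Returns role-recovery accuracy, genus-level 16S assignment accuracy
    for in-reference amplicons, median bin purity and the number of
    genomes reaching completeness >= 0.75.
    """
    reference = refs.get_references()
    tree = default_taxonomy()
    genomes, profiles = synth.simulate_default_community(
        seed=stage_seed(seed, "simulate"), n_samples=n_samples
    )
    rng = np.random.default_rng(stage_seed(seed, "derive"))

    # 16S profiling
    model = amp.train_word_model(
        synth.make_16s_reference(seed=stage_seed(seed, "ref16s")), tree
    )
    correct = total = 0
    for profile in profiles:
        pairs, truth = synth.simulate_amplicons(
            genomes, profile, n_pairs=amplicon_pairs,
            seed=int(rng.integers(2**31)),
        )
        genus_truth = dict(zip(truth["read"], truth["genus"]))
        for f, r in pairs:
            m = amp.merge_pairs(f, r)
            if m is None:
                continue
            kept, _ = amp.filter_sequences([m])
            if not kept:
                continue
            conf = amp.classify_with_bootstrap(model, m.bases,
                                               seed=int(rng.integers(2**31)))
            a = amp.escalate_assignment(conf, read_id=m.id)
            total += 1
            if a.accepted_rank == "genus" and a.display_name == genus_truth[m.id]:
                correct += 1
    amplicon_accuracy = correct / total if total else 0.0

    # contigs, annotation, roles
    contig_sets = [
        synth.shear_contigs_per_genome(genomes, contigs_per_genome,
                                       seed=int(rng.integers(2**31)),
                                       prefix=f"{p.sample}_c")
        for p in profiles
    ]
    contigs = [c for cs in contig_sets for c in cs.contigs]
    _genes, _hits, table = ann.annotate_contigs(contigs, reference)
    matrix = rl.build_gene_content_matrix(table, grouping="genus",
                                          groups=[g.genus for g in genomes])
    calls = rl.classify_roles(matrix)
    truth_roles = {g.genus: g.role for g in genomes}
    _cm, role_accuracy = rl.role_recovery(
        [a for a in calls if a.taxon in truth_roles], truth_roles
    )

    # binning
    sigs = bng.signatures_for(contigs)
    coords = bng.embed(sigs, seed=stage_seed(seed, "bin"))
    bins, _noise = bng.cluster_embedding(coords)
    gm = {g.id: g for g in genomes}
    truth = pd.concat([cs.truth(gm) for cs in contig_sets], ignore_index=True)
    truth = truth[truth["contig"].isin(coords.index)]
    purity, completeness = bng.bin_quality(bins, truth)
    return {
        "role_accuracy": role_accuracy,
        "amplicon_genus_accuracy": amplicon_accuracy,
        "median_bin_purity": float(purity["purity"].median()) if len(purity) else 0.0,
        "n_complete_genomes": int((completeness["completeness"] >= 0.75).sum()),
        "n_genomes": len(genomes),
        "n_contigs": len(contigs),
        "n_reads": total,
    }
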