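"""End-to-end orchestration: simulate -> annotate -> align -> analyse.

A :class:`PipelineRun` owns one output directory with a fixed layout::

    truth/        simulated segments, genes and ground-truth tables
    annotation/   recovered features, spacers and tRNA loops (+ GFF3)
    alignments/   per-gene alignments (codon-aware for PCGs)
    concat/       named concatenations with RAxML-style partition files
    distances/    p-distance matrices and clade summaries
    signal/       quartet likelihood-mapping report
    signatures/   spacer presence patterns and diagnostic loop motifs
    traits/       parsimony reconstructions and convergence summary
    evaluation.json, manifest.json

Every stage can be re-run from disk, so the CLI subcommands are thin
wrappers.  All randomness flows from the single seed in the simulation
config; re-running a stage with the same inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import alignkit, cladedist, geneorder as go, mitoannot, signatures, \
    synthgen, traitmap, treesignal

__all__ = ["PipelineRun", "canonical_trna_track", "run_pipeline",
           "table3_summary"]

_VERSION = "0.1.0"


def canonical_trna_track() -> alignkit.StructureTrack:
    """Structure track of the canonical 70-nt cloverleaf template."""
    geo = go.TRNA_GEOMETRY
    order = [("acceptor", "stem"), ("linker1", "unpaired"),
             ("d_stem", "stem"), ("dhu_loop", "loop"), ("d_stem'", "stem"),
             ("linker2", "unpaired"), ("ac_stem", "stem"),
             ("ac_loop", "loop"), ("ac_stem'", "stem"),
             ("var_loop", "loop"), ("t_stem", "stem"), ("t_loop", "loop"),
             ("t_stem'", "stem"), ("acceptor'", "stem")]
    ann, spans = [], {}
    pos = 0
    for part, kind in order:
        n = geo[part.rstrip("'")]
        spans[part] = (pos, pos + n)
        ann.extend([kind] * n)
        pos += n
    partner = [-1] * pos
    for a, b in [("acceptor", "acceptor'"), ("d_stem", "d_stem'"),
                 ("ac_stem", "ac_stem'"), ("t_stem", "t_stem'")]:
        (s1, e1), (s2, e2) = spans[a], spans[b]
        for k in range(e1 - s1):
            partner[s1 + k] = e2 - 1 - k
            partner[e2 - 1 - k] = s1 + k
    return alignkit.StructureTrack(ann, partner)


def table3_summary(matrix_tsv, tree_nwk, clades_tsv,
                   n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Clade summary straight from a printed distance-matrix TSV."""
    matrix = cladedist.DistanceMatrix.from_tsv(matrix_tsv)
    model = cladedist.CladeModel.from_files(tree_nwk, clades_tsv)
    return cladedist.clade_summary(matrix, model, n_boot=n_boot, seed=seed)


class PipelineRun:
    """One pipeline run rooted at *run_dir* (created on demand)."""

    def __init__(self, run_dir, config: synthgen.SimulationConfig | None = None,
                 seed: int | None = None):
        self.dir = Path(run_dir)
        if config is None:
            config = synthgen.default_config(seed if seed is not None else 0)
        elif seed is not None and seed != config.seed:
            raise ValueError("seed given both directly and in the config")
        self.config = config
        self.truth: synthgen.TruthBundle | None = None
        self.annotations = None
        self.alignments: dict[str, alignkit.Alignment] | None = None
        self.concats = None
        self._written: list[Path] = []

    # -- plumbing ------------------------------------------------------------

    def _path(self, *parts) -> Path:
        p = self.dir.joinpath(*parts)
        p.parent.mkdir(parents=True, exist_ok=True)
        self._written.append(p)
        return p

    def _need_truth(self) -> synthgen.TruthBundle:
        if self.truth is None:
            truth_dir = self.dir / "truth"
            if not (truth_dir / "tree.nwk").exists():
                raise FileNotFoundError(
                    "stage 'simulate' has not been run (missing truth/)")
            self.truth = synthgen.TruthBundle.read(truth_dir, self.config)
        return self.truth

    def _need_annotation_tables(self):
        feats = self.dir / "annotation" / "features.tsv"
        if not feats.exists():
            raise FileNotFoundError(
                "stage 'annotate' has not been run (missing annotation/)")
        read = lambda name, **kw: pd.read_csv(
            self.dir / "annotation" / name, sep="\t", **kw)
        spacers = read("spacers.tsv", keep_default_na=False,
                       dtype={"sequence": str})
        spacers["present"] = spacers["present"].map(
            lambda v: v if isinstance(v, (bool, np.bool_))
            else str(v) == "True")
        return read("features.tsv"), spacers, read("loops.tsv")

    # -- stages --------------------------------------------------------------

    def simulate(self) -> synthgen.TruthBundle:
        self.truth = synthgen.simulate(self.config)
        self.truth.write(self.dir / "truth")
        return self.truth

    def annotate(self):
        truth = self._need_truth()
        self.annotations = {taxon: mitoannot.annotate_genome(segs)
                            for taxon, segs in truth.segments.items()}
        feats = mitoannot.features_table(self.annotations)
        feats.to_csv(self._path("annotation", "features.tsv"),
                     sep="\t", index=False)
        mitoannot.spacers_table(self.annotations).to_csv(
            self._path("annotation", "spacers.tsv"), sep="\t", index=False)
        mitoannot.loops_table(self.annotations).to_csv(
            self._path("annotation", "loops.tsv"), sep="\t", index=False)
        for taxon, per_seg in self.annotations.items():
            with open(self._path("annotation", "gff", f"{taxon}.gff3"),
                      "w") as fh:
                fh.write(mitoannot.to_gff3(taxon, per_seg))
        return self.annotations

    def gene_sequences(self) -> dict[str, dict[str, str]]:
        """Per-gene coding-orientation sequences from the *annotation*
        (nuclear genes straight from the truth bundle, as sequenced CDSs)."""
        truth = self._need_truth()
        features, _, _ = self._need_annotation_tables()
        out: dict[str, dict[str, str]] = {}
        for _, row in features.iterrows():
            seq = truth.segments[row["taxon"]][row["segment"]]
            sub = seq[row["start"]:row["end"]]
            if row["strand"] == "-":
                sub = mitoannot.revcomp(sub)
            out.setdefault(row["gene"], {})[row["taxon"]] = sub
        for gene in go.NUCLEAR_GENES:
            if gene in truth.genes:
                out[gene] = dict(truth.genes[gene])
        return out

    def align(self) -> dict[str, alignkit.Alignment]:
        genes = self.gene_sequences()
        track = canonical_trna_track()
        nt = alignkit.nucleotide_scorer()
        pcgs = {ft.gene for seg in go.SEGMENT_IDS
                for ft in go.SEGMENTS[seg] if ft.type == "PCG"}
        trnas = {ft.gene for seg in go.SEGMENT_IDS
                 for ft in go.SEGMENTS[seg] if ft.type == "tRNA"}
        self.alignments = {}
        for gene, seqs in sorted(genes.items()):
            if gene == "AT_rich":
                continue
            names = sorted(seqs)
            if gene in pcgs or gene in go.NUCLEAR_GENES:
                aln = alignkit.codon_align({n: seqs[n] for n in names})
            elif gene in trnas:
                template = next((n for n in names
                                 if len(seqs[n]) == len(track)), None)
                if template is not None:
                    aln = alignkit.structure_align(
                        {n: seqs[n] for n in names}, track,
                        template_taxon=template)
                else:
                    aln = alignkit.progressive_align(
                        names, [seqs[n] for n in names], nt, role="tRNA")
            else:
                aln = alignkit.progressive_align(
                    names, [seqs[n] for n in names], nt, role="rRNA")
            self.alignments[gene] = aln
            alignkit.write_fasta(aln.as_dict(),
                                 self._path("alignments", f"{gene}.fasta"))
        return self.alignments

    def _need_alignments(self) -> dict[str, alignkit.Alignment]:
        if self.alignments is None:
            adir = self.dir / "alignments"
            if not adir.exists():
                raise FileNotFoundError(
                    "stage 'align' has not been run (missing alignments/)")
            pcgs = {ft.gene for seg in go.SEGMENT_IDS
                    for ft in go.SEGMENTS[seg] if ft.type == "PCG"}
            self.alignments = {}
            for path in sorted(adir.glob("*.fasta")):
                gene = path.stem
                role = ("PCG_nt" if gene in pcgs or gene in go.NUCLEAR_GENES
                        else "tRNA")
                self.alignments[gene] = alignkit.alignment_from_fasta(
                    str(path), role=role)
        return self.alignments

    def concat(self, sets: list[str] | None = None):
        alns = self._need_alignments()
        if sets is None:
            sets = [s for s in alignkit.NAMED_SETS
                    if all(g in alns for g in alignkit.NAMED_SETS[s]["genes"])]
        self.concats = {}
        for set_name in sets:
            aln, scheme = alignkit.concatenate(alns, set_name)
            self.concats[set_name] = (aln, scheme)
            alignkit.write_fasta(aln.as_dict(),
                                 self._path("concat", f"{set_name}.fasta"))
            with open(self._path("concat", f"{set_name}.partitions"),
                      "w") as fh:
                fh.write(scheme.to_raxml())
        return self.concats

    def _need_concats(self):
        if self.concats is None:
            cdir = self.dir / "concat"
            if not cdir.exists():
                raise FileNotFoundError(
                    "stage 'concat' has not been run (missing concat/)")
            self.concats = {}
            for path in sorted(cdir.glob("*.fasta")):
                aln = alignkit.alignment_from_fasta(str(path),
                                                    role="concatenated")
                self.concats[path.stem] = (aln, None)
        return self.concats

    def distances(self, n_boot: int = 1000):
        concats = self._need_concats()
        truth = self._need_truth()
        out = {}
        for set_name, (aln, _) in sorted(concats.items()):
            matrix = cladedist.p_distance_matrix(aln)
            matrix.to_tsv(self._path("distances", f"{set_name}.tsv"),
                          decimals=6)
            summary = cladedist.clade_summary(
                matrix, truth.clade_map, n_boot=n_boot,
                seed=self.config.seed)
            summary.to_csv(
                self._path("distances", f"{set_name}_clades.tsv"),
                sep="\t", index=False)
            nj = treesignal.nj_tree(matrix)
            with open(self._path("distances", f"{set_name}_nj.nwk"),
                      "w") as fh:
                fh.write(nj.newick() + "\n")
            out[set_name] = (matrix, summary)
        return out

    def signal(self, sets: list[str] | None = None,
               n_quartets: int = 150) -> pd.DataFrame:
        concats = self._need_concats()
        if sets is None:
            sets = [s for s in ("mtpcg", "nuc3", "7trnas") if s in concats]
        named = {s: concats[s][0] for s in sets}
        n_taxa = min(len(a) for a in named.values())
        total = (n_taxa * (n_taxa - 1) * (n_taxa - 2) * (n_taxa - 3)) // 24
        sample = "all" if total <= n_quartets else (n_quartets,
                                                    self.config.seed)
        report = treesignal.signal_report(named, quartet_sample=sample)
        report.to_csv(self._path("signal", "signal.tsv"), sep="\t",
                      index=False)
        return report

    def signatures_stage(self):
        truth = self._need_truth()
        _, spacers, loops = self._need_annotation_tables()
        groups = signatures.group_spacers(spacers)
        patterns, table = signatures.classify_all(truth.tree, groups)
        table.to_csv(self._path("signatures", "spacer_patterns.tsv"),
                     sep="\t", index=False)
        motifs = signatures.diagnostic_motifs(loops, truth.clade_map)
        motifs.to_csv(self._path("signatures", "diagnostic_motifs.tsv"),
                      sep="\t", index=False)
        return patterns, motifs

    def traits_stage(self):
        truth = self._need_truth()
        results, summary = traitmap.map_all_traits(truth.tree, truth.traits)
        summary.to_csv(self._path("traits", "summary.tsv"), sep="\t",
                       index=False)
        for trait, res in results.items():
            with open(self._path("traits", f"{trait}.nwk"), "w") as fh:
                fh.write(res.annotated_newick(truth.tree) + "\n")
        return results, summary

    # -- evaluation against the truth -----------------------------------------

    def evaluate(self) -> dict:
        truth = self._need_truth()
        features, spacers, loops = self._need_annotation_tables()
        metrics: dict = {}

        # exact PCG boundary recovery (both ends must match)
        t = truth.features.query("type == 'PCG'")
        a = features.query("type == 'PCG'")
        key = ["taxon", "segment", "gene"]
        merged = t.merge(a, on=key, suffixes=("_t", "_a"), how="left")
        exact = ((merged["start_t"] == merged["start_a"])
                 & (merged["end_t"] == merged["end_a"]))
        metrics["pcg_boundary_recovery_pct"] = round(
            100.0 * float(exact.mean()), 3)
        metrics["n_pcg_records"] = int(len(merged))

        trunc_genes = [(seg, ft.gene) for seg in go.SEGMENT_IDS
                       for ft in go.SEGMENTS[seg]
                       if ft.type == "PCG" and ft.stop in ("T", "TA")]
        trunc_mask = merged.apply(
            lambda r: (r["segment"], r["gene"]) in trunc_genes, axis=1)
        trunc_ok = merged.loc[trunc_mask, "truncated_stop"].fillna(False)
        metrics["truncated_stop_recovery_pct"] = round(
            100.0 * float((trunc_ok & exact[trunc_mask]).mean()), 3) \
            if trunc_mask.any() else 100.0

        # tRNA recovery: boundaries and anticodon-bearing fold found
        tt = truth.features.query("type == 'tRNA'")
        ta = features.query("type == 'tRNA'")
        merged_t = tt.merge(ta, on=key, suffixes=("_t", "_a"), how="left")
        found = merged_t["start_a"].notna()
        metrics["trna_detection_pct"] = round(100.0 * float(found.mean()), 3)
        exact_t = ((merged_t["start_t"] == merged_t["start_a"])
                   & (merged_t["end_t"] == merged_t["end_a"]))
        metrics["trna_boundary_recovery_pct"] = round(
            100.0 * float(exact_t.mean()), 3)

        # spacer presence/absence pattern recovery per locus
        def patterns(df):
            out = {}
            for locus, sub in df.groupby("locus"):
                out[locus] = frozenset(sub.loc[sub["present"].astype(bool),
                                               "taxon"])
            return out
        tp, ap = patterns(truth.spacers), patterns(spacers)
        loci = sorted(set(tp) | set(ap))
        ok = sum(tp.get(l, frozenset()) == ap.get(l, frozenset())
                 for l in loci)
        metrics["spacer_pattern_recovery_pct"] = round(
            100.0 * ok / len(loci), 3) if loci else 100.0

        # diagnostic motifs: recovery of injected clade-wide loop events and
        # false positives by re-matching
        motifs = signatures.diagnostic_motifs(loops, truth.clade_map)
        seq_of = {(r["taxon"], r["trna"], r["loop"]): r["sequence"]
                  for _, r in loops.iterrows()}
        fp = 0
        for _, m in motifs.iterrows():
            members = {t for t, c in truth.clade_map.items()
                       if c == m["clade"]}
            matching = {t for t, c in truth.clade_map.items()
                        if (t, m["trna"], m["loop"]) in seq_of
                        and signatures.matches_iupac(
                            seq_of[(t, m["trna"], m["loop"])], m["motif"])}
            if matching != members:
                fp += 1
        metrics["diagnostic_motif_false_positives"] = fp
        metrics["n_diagnostic_motifs"] = int(len(motifs))

        # trait convergence from the reconstruction
        for spec in self.config.traits:
            for state in spec.states:
                column = truth.traits.column(spec.name)
                n = traitmap.count_min_origins(truth.tree, column, state,
                                               states=list(spec.states))
                metrics[f"origins[{spec.name}={state}]"] = n

        with open(self._path("evaluation.json"), "w") as fh:
            json.dump(metrics, fh, indent=2, sort_keys=True)
        return metrics

    # -- manifest --------------------------------------------------------------

    def write_manifest(self) -> dict:
        checksums = {}
        for path in sorted(set(self._written)):
            if path.is_file():
                rel = str(path.relative_to(self.dir))
                checksums[rel] = hashlib.sha256(
                    path.read_bytes()).hexdigest()
        manifest = {
            "tool": "mitosig",
            "version": _VERSION,
            "seed": self.config.seed,
            "config": synthgen.config_to_dict(self.config),
            "outputs": checksums,
        }
        with open(self.dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest

    def run_all(self, n_quartets: int = 150, n_boot: int = 1000) -> dict:
        self.simulate()
        self.annotate()
        self.align()
        self.concat()
        self.distances(n_boot=n_boot)
        self.signal(n_quartets=n_quartets)
        self.signatures_stage()
        self.traits_stage()
        self.evaluate()
        return self.write_manifest()


def run_pipeline(run_dir, seed: int = 0,
                 config: synthgen.SimulationConfig | None = None,
                 n_quartets: int = 150) -> dict:
    """Convenience wrapper: full synthetic run under *run_dir*."""
    run = PipelineRun(run_dir, config=config,
                      seed=None if config is not None else seed)
    return run.run_all(n_quartets=n_quartets)
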