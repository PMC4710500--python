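"""End-to-end orchestration of the analysis workflow.

Two layers: :func:`analyze` runs the whole method in memory (filter ->
assemble -> call ORFs -> map & quantify -> annotate -> classify) and is
what the tests and benchmark harness call; :func:`run_pipeline` is the
file-based front end used by the CLI, with per-stage checksummed outputs
so an interrupted or partially stale run resumes only the stages whose
inputs changed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import annotation as ann
from . import assembler, genecalling, preprocess, taxonomy
from .formats import SequenceRecord


@dataclass
class PipelineConfig:
    filter: preprocess.FilterConfig = field(default_factory=preprocess.FilterConfig)
    k_list: tuple[int, ...] = (31, 41, 51)
    min_count: int = 1
    min_contig_len: int | None = None
    min_orf_aa: int = 60
    min_partial_aa: int = 30
    seed_k: int = 21
    max_mismatch: int = 3
    lca: taxonomy.LcaParams = field(default_factory=taxonomy.LcaParams)
    tax_rank: str = "order"
    min_srv: float = 0.5
    min_marker_count: int = 1
    taxonomy_mode: str = "two_step"  # or "one_step"
    exclude_taxids: tuple[int, ...] = ()


@dataclass
class PipelineResult:
    clean_reads: list[SequenceRecord]
    filter_report: preprocess.FilterReport
    contigs: list[assembler.Contig]
    orfs: list[genecalling.Orf]
    placements: dict[str, genecalling.Placement | None]
    expression: genecalling.ExpressionTable
    hits: dict[str, list[ann.Hit]]
    annotations: dict[str, ann.Annotation]
    srv_scores: dict[str, float]
    protein_taxids: dict[str, int | None]
    read_ko: dict[str, str | None]
    read_taxid: dict[str, int | None]

    def ko_profile(self) -> dict[str, int]:
        """Read counts per KO, summed over annotated ORFs."""
        profile: dict[str, int] = {}
        for rid, ko in self.read_ko.items():
            if ko:
                profile[ko] = profile.get(ko, 0) + 1
        return profile


def analyze(
    reads: Sequence[SequenceRecord],
    rrna_refs: Sequence[SequenceRecord | str],
    db: ann.ReferenceProteinDB,
    tree: taxonomy.TaxonomyTree,
    marker_db: ann.ReferenceProteinDB | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the complete in-memory workflow on raw reads.

    Per-read function (KO) and taxon predictions are derived by pushing
    each mapped read through its assigned ORF's annotation/classification;
    unmapped, intergenic and unannotated reads predict None.
    """
    config = config or PipelineConfig()
    clean, report = preprocess.run_filters(reads, rrna_refs, config.filter)

    contigs = assembler.assemble_multi_k(
        clean,
        k_list=config.k_list,
        min_count=config.min_count,
        min_contig_len=config.min_contig_len,
        compute_coverage=False,
    )
    orfs = []
    for contig in contigs:
        orfs.extend(
            genecalling.call_orfs(
                contig,
                min_orf_aa=config.min_orf_aa,
                min_partial_aa=config.min_partial_aa,
            )
        )
    # annotate every ORF call first: homology to the reference database is
    # the best evidence for the true reading frame and steers the overlap
    # resolution below
    all_proteins = {o.id: o.protein for o in orfs if o.protein}
    exclude = set(config.exclude_taxids) or None
    search_db = db.exclude(exclude) if exclude else db
    hits = ann.search(all_proteins, search_db)
    annotations = ann.annotate_sbh(hits, search_db)
    with_hits = {pid for pid, hl in hits.items() if hl}
    orfs = genecalling.resolve_overlaps(orfs, annotated=with_hits)

    placements = genecalling.map_reads(
        clean, contigs, seed_k=config.seed_k, max_mismatch=config.max_mismatch
    )
    for contig in contigs:  # read-based mean coverage
        contig.mean_coverage = 0.0
    by_id = {c.id: c for c in contigs}
    for pl in placements.values():
        if pl is not None:
            by_id[pl.contig_id].mean_coverage += pl.length
    for contig in contigs:
        contig.mean_coverage /= len(contig)
    expression = genecalling.quantify(placements, orfs)

    proteins = {o.id: o.protein for o in orfs if o.protein}
    srv_scores = {
        pid: ann.srv(proteins[pid], hits.get(pid, []), query_id=pid).srv
        for pid in proteins
    }

    if config.taxonomy_mode == "two_step":
        if marker_db is None:
            raise ValueError("two-step taxonomy requires a marker database")
        two = taxonomy.classify_two_step(
            proteins,
            db,
            tree,
            marker_db,
            params=config.lca,
            rank=config.tax_rank,
            min_srv=config.min_srv,
            min_marker_count=config.min_marker_count,
            exclude_taxids=exclude,
        )
        protein_taxids = two.assignments
    else:
        protein_taxids = taxonomy.classify_one_step(
            proteins, db, tree, params=config.lca, exclude_taxids=exclude
        )

    read_ko: dict[str, str | None] = {}
    read_taxid: dict[str, int | None] = {}
    for rid, orf_id in expression.read_orf.items():
        if orf_id is None:
            read_ko[rid] = None
            read_taxid[rid] = None
            continue
        a = annotations.get(orf_id)
        read_ko[rid] = a.ko if a and a.ko else None
        read_taxid[rid] = protein_taxids.get(orf_id)

    return PipelineResult(
        clean,
        report,
        contigs,
        orfs,
        placements,
        expression,
        hits,
        annotations,
        srv_scores,
        protein_taxids,
        read_ko,
        read_taxid,
    )


# --- file-based staged pipeline -------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _params_hash(params: dict) -> str:
    return hashlib.sha256(
        json.dumps(params, sort_keys=True, default=str).encode()
    ).hexdigest()


class StageRunner:
    """Checksummed stage execution: a stage reruns iff its inputs, its
    parameters or its recorded outputs changed since the manifest entry."""

    def __init__(self, outdir: Path, log=None):
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.outdir / "manifest.json"
        self.manifest: dict = {"stages": {}}
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())
        self.log = log or (lambda msg: None)

    def run(self, name: str, inputs: list[Path], outputs: list[Path],
            params: dict, fn) -> bool:
        entry = {
            "inputs": {str(p): _sha256(p) for p in inputs if p.exists()},
            "params": _params_hash(params),
        }
        prev = self.manifest["stages"].get(name)
        if (
            prev
            and prev["inputs"] == entry["inputs"]
            and prev["params"] == entry["params"]
            and all(p.exists() for p in outputs)
            and prev.get("outputs")
            == {str(p): _sha256(p) for p in outputs if p.exists()}
        ):
            self.log(f"stage {name}: up to date, skipped")
            return False
        t0 = time.monotonic()
        fn()
        entry["outputs"] = {str(p): _sha256(p) for p in outputs if p.exists()}
        self.manifest["stages"][name] = entry
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2))
        self.log(f"stage {name}: done in {time.monotonic() - t0:.1f}s")
        return True


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(
    outdir: str | Path,
    reads_path: str | Path,
    rrna_path: str | Path,
    db_fasta: str | Path,
    db_labels: str | Path,
    nodes_path: str | Path,
    names_path: str | Path,
    marker_fasta: str | Path | None = None,
    marker_labels: str | Path | None = None,
    truth_path: str | Path | None = None,
    config: PipelineConfig | None = None,
    log=None,
) -> Path:
    """Run the staged workflow from files into ``outdir``.

    Emits clean.fastq, contigs.fasta, orfs.gff3, proteins.faa,
    expression.tsv, annotations.tsv, srv.tsv, cog_profile.tsv,
    classifications.tsv, tax_profile.tsv, read_predictions.tsv and (when a
    truth table is given) pr_report.tsv, plus manifest.json recording
    checksums and parameters.
    """
    from . import evaluation, formats, simulate

    config = config or PipelineConfig()
    outdir = Path(outdir)
    runner = StageRunner(outdir, log=log)
    reads_path, rrna_path = Path(reads_path), Path(rrna_path)

    clean_path = outdir / "clean.fastq"
    report_path = outdir / "filter_report.tsv"

    def stage_filter():
        reads = list(formats.read_fastq(reads_path))
        rrna = list(formats.read_fasta(rrna_path))
        clean, report = preprocess.run_filters(reads, rrna, config.filter)
        formats.write_fastq(clean, clean_path)
        _write_tsv(report.to_frame(), report_path)

    runner.run(
        "filter",
        [reads_path, rrna_path],
        [clean_path, report_path],
        asdict(config.filter),
        stage_filter,
    )

    contigs_path = outdir / "contigs.fasta"

    def stage_assemble():
        clean = list(formats.read_fastq(clean_path))
        contigs = assembler.assemble_multi_k(
            clean,
            k_list=config.k_list,
            min_count=config.min_count,
            min_contig_len=config.min_contig_len,
        )
        assembler.write_contigs(contigs, contigs_path)

    runner.run(
        "assemble",
        [clean_path],
        [contigs_path],
        {"k_list": config.k_list, "min_count": config.min_count,
         "min_contig_len": config.min_contig_len},
        stage_assemble,
    )

    orfs_path = outdir / "orfs.gff3"
    proteins_path = outdir / "proteins.faa"

    def stage_orfs():
        contigs = assembler.import_contigs(contigs_path)
        orfs = []
        for contig in contigs:
            orfs.extend(
                genecalling.call_orfs(
                    contig,
                    min_orf_aa=config.min_orf_aa,
                    min_partial_aa=config.min_partial_aa,
                )
            )
        formats.write_gff3(genecalling.orfs_to_features(orfs), orfs_path)
        formats.write_fasta(
            (SequenceRecord(o.id, o.protein) for o in orfs if o.protein),
            proteins_path,
        )

    runner.run(
        "call-orfs",
        [contigs_path],
        [orfs_path, proteins_path],
        {"min_orf_aa": config.min_orf_aa, "min_partial_aa": config.min_partial_aa},
        stage_orfs,
    )

    db_fasta, db_labels = Path(db_fasta), Path(db_labels)
    ann_path = outdir / "annotations.tsv"
    srv_path = outdir / "srv.tsv"

    def stage_annotate():
        db = ann.ReferenceProteinDB.from_files(db_fasta, db_labels)
        if config.exclude_taxids:
            db = db.exclude(set(config.exclude_taxids))
        proteins = {r.id: r.seq for r in formats.read_fasta(proteins_path)}
        hits = ann.search(proteins, db)
        annotations = ann.annotate_sbh(hits, db)
        srv_scores = {
            pid: ann.srv(proteins[pid], hits.get(pid, []), query_id=pid).srv
            for pid in sorted(proteins)
        }
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "orf_id": a.query_id,
                        "subject_id": a.subject_id,
                        "ko": a.ko,
                        "cog": a.cog,
                        "categories": a.categories,
                        "n_hits": len(hits.get(a.query_id, [])),
                    }
                    for a in (annotations[p] for p in sorted(annotations))
                ]
            ),
            ann_path,
        )
        _write_tsv(
            pd.DataFrame(
                [{"orf_id": p, "srv": s} for p, s in srv_scores.items()]
            ),
            srv_path,
        )

    runner.run(
        "annotate",
        [proteins_path, db_fasta, db_labels],
        [ann_path, srv_path],
        {"exclude_taxids": config.exclude_taxids},
        stage_annotate,
    )

    expr_path = outdir / "expression.tsv"
    assign_path = outdir / "read_assignments.tsv"
    cog_path = outdir / "cog_profile.tsv"

    def stage_quantify():
        clean = list(formats.read_fastq(clean_path))
        contigs = assembler.import_contigs(contigs_path)
        orfs = _orfs_from_gff(outdir, contigs)
        anns = pd.read_csv(ann_path, sep="\t", keep_default_na=False)
        with_hits = set(anns.loc[anns["n_hits"] > 0, "orf_id"])
        orfs = genecalling.resolve_overlaps(orfs, annotated=with_hits)
        placements = genecalling.map_reads(
            clean, contigs, seed_k=config.seed_k, max_mismatch=config.max_mismatch
        )
        expr = genecalling.quantify(placements, orfs)
        _write_tsv(expr.table, expr_path)
        rows = [
            {"read_id": rid, "orf_id": oid if oid else ""}
            for rid, oid in sorted(expr.read_orf.items())
        ]
        unmapped = [
            {"read_id": rid, "orf_id": "*"}
            for rid, pl in sorted(placements.items())
            if pl is None
        ]
        _write_tsv(pd.DataFrame(rows + unmapped, columns=["read_id", "orf_id"]),
                   assign_path)
        counts = dict(zip(expr.table["orf_id"], expr.table["read_count"]))
        annotations = {
            row.orf_id: ann.Annotation(
                row.orf_id, row.subject_id, row.ko, row.cog, row.categories
            )
            for row in anns.itertuples()
        }
        _write_tsv(ann.lump_cog_categories(counts, annotations), cog_path)

    runner.run(
        "quantify",
        [clean_path, contigs_path, orfs_path, ann_path],
        [expr_path, assign_path, cog_path],
        {"seed_k": config.seed_k, "max_mismatch": config.max_mismatch},
        stage_quantify,
    )

    cls_path = outdir / "classifications.tsv"
    tax_profile_path = outdir / "tax_profile.tsv"
    nodes_path, names_path = Path(nodes_path), Path(names_path)

    def stage_classify():
        tree = taxonomy.TaxonomyTree.from_files(nodes_path, names_path)
        db = ann.ReferenceProteinDB.from_files(db_fasta, db_labels)
        expr = pd.read_csv(expr_path, sep="\t")
        retained = set(expr["orf_id"])
        proteins = {
            r.id: r.seq
            for r in formats.read_fasta(proteins_path)
            if r.id in retained
        }
        exclude = set(config.exclude_taxids) or None
        if config.taxonomy_mode == "two_step":
            marker_db = ann.ReferenceProteinDB.from_files(
                marker_fasta, marker_labels
            )
            result = taxonomy.classify_two_step(
                proteins, db, tree, marker_db,
                params=config.lca, rank=config.tax_rank,
                min_srv=config.min_srv,
                min_marker_count=config.min_marker_count,
                exclude_taxids=exclude,
            )
            assignments = result.assignments
        else:
            assignments = taxonomy.classify_one_step(
                proteins, db, tree, params=config.lca, exclude_taxids=exclude
            )
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "orf_id": pid,
                        "taxid": t if t is not None else -1,
                        "rank_path": tree.rank_path(t) if t is not None else "",
                    }
                    for pid, t in sorted(assignments.items())
                ]
            ),
            cls_path,
        )
        expr = pd.read_csv(expr_path, sep="\t")
        counts = dict(zip(expr["orf_id"], expr["read_count"]))
        profile = taxonomy.taxonomic_profile(
            assignments, counts, tree, config.tax_rank
        )
        _write_tsv(profile, tax_profile_path)

    classify_inputs = [proteins_path, expr_path, db_fasta, db_labels,
                       nodes_path, names_path]
    if marker_fasta:
        classify_inputs += [Path(marker_fasta), Path(marker_labels)]
    runner.run(
        "classify",
        classify_inputs,
        [cls_path, tax_profile_path],
        {
            "mode": config.taxonomy_mode,
            "rank": config.tax_rank,
            "lca": asdict(config.lca),
            "min_srv": config.min_srv,
            "min_marker_count": config.min_marker_count,
            "exclude_taxids": config.exclude_taxids,
        },
        stage_classify,
    )

    pred_path = outdir / "read_predictions.tsv"

    def stage_predictions():
        assigns = pd.read_csv(assign_path, sep="\t", keep_default_na=False)
        anns = pd.read_csv(ann_path, sep="\t", keep_default_na=False).set_index(
            "orf_id"
        )
        cls = pd.read_csv(cls_path, sep="\t", keep_default_na=False).set_index(
            "orf_id"
        )
        rows = []
        for rid, oid in zip(assigns["read_id"], assigns["orf_id"]):
            ko, taxid = "", -1
            if oid and oid != "*":
                if oid in anns.index:
                    ko = anns.at[oid, "ko"]
                if oid in cls.index:
                    taxid = int(cls.at[oid, "taxid"])
            rows.append({"read_id": rid, "ko": ko, "taxid": taxid})
        _write_tsv(pd.DataFrame(rows), pred_path)

    runner.run(
        "read-predictions",
        [assign_path, ann_path, cls_path],
        [pred_path],
        {},
        stage_predictions,
    )

    if truth_path is not None:
        truth_path = Path(truth_path)
        pr_path = outdir / "pr_report.tsv"

        def stage_evaluate():
            truth = simulate.read_truth(truth_path)
            pred = pd.read_csv(pred_path, sep="\t", keep_default_na=False)
            tree = taxonomy.TaxonomyTree.from_files(nodes_path, names_path)
            mrna = truth[truth["molecule"] == "mRNA"]
            truth_ko = dict(zip(mrna["read_id"], mrna["ko"]))
            truth_tax = dict(zip(mrna["read_id"], mrna["taxid"]))
            pred_ko = {
                r: (k if k else None)
                for r, k in zip(pred["read_id"], pred["ko"])
                if r in truth_ko
            }
            pred_tax = {
                r: (int(t) if int(t) >= 0 else None)
                for r, t in zip(pred["read_id"], pred["taxid"])
                if r in truth_tax
            }
            reports = {"function": evaluation.functional_pr(truth_ko, pred_ko)}
            reports.update(
                evaluation.taxonomic_pr(truth_tax, pred_tax, tree)
            )
            _write_tsv(evaluation.pr_table(reports), pr_path)

        runner.run(
            "evaluate",
            [pred_path, truth_path, nodes_path, names_path],
            [pr_path],
            {},
            stage_evaluate,
        )

    return outdir


def _orfs_from_gff(outdir: Path, contigs) -> list[genecalling.Orf]:
    """Rehydrate ORFs from the stage outputs (gff3 + proteins.faa)."""
    from .formats import read_fasta, read_gff3

    prots = {r.id: r.seq for r in read_fasta(outdir / "proteins.faa")}
    orfs = []
    for row in read_gff3(outdir / "orfs.gff3"):
        oid = row.attrs["ID"]
        orfs.append(
            genecalling.Orf(
                id=oid,
                contig_id=row.seq_id,
                start=row.start - 1,
                end=row.end,
                strand=row.strand,
                frame=0,
                partial5=row.attrs.get("partial5") == "true",
                partial3=row.attrs.get("partial3") == "true",
                protein=prots.get(oid, ""),
            )
        )
    return orfs
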