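"""Standard validation experiments run on simulated mock communities.

Each function here sets up a defined study condition (community design,
coverage, error and contamination rates), runs the relevant slice of the
pipeline from scratch and measures the outcome.  They are used both by the
acceptance test-suite and by ``scripts/acceptance.py``; all randomness is
controlled by the single seed argument.
"""

from __future__ import annotations

import filecmp
from pathlib import Path

import numpy as np

from . import evaluation, pipeline, preprocess, simulate, taxonomy
from .assembler import assemble_multi_k, canonical, canonical_seq
from .formats import SequenceRecord


def _random_seq(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _repeat_free(seq: str, k: int) -> bool:
    kmers = [canonical(seq[i : i + k - 1]) for i in range(len(seq) - k + 2)]
    return len(kmers) == len(set(kmers))


def assembler_recovery(seed: int, n_transcripts: int = 50) -> dict:
    """Error-free reconstruction rate over random repeat-free transcripts.

    Each 1-3 kb transcript is tiled by error-free 75-mers (step 5, both
    ends covered) and assembled on its own; success means exactly one
    contig equal to the source up to reverse complement.
    """
    rng = np.random.default_rng(seed)
    n_ok = 0
    done = 0
    while done < n_transcripts:
        seq = _random_seq(rng, int(rng.integers(1000, 3001)))
        if not _repeat_free(seq, 31):
            continue
        done += 1
        starts = list(range(0, len(seq) - 75 + 1, 5))
        if starts[-1] != len(seq) - 75:
            starts.append(len(seq) - 75)
        reads = [
            SequenceRecord(f"r{i}", seq[s : s + 75], [38] * 75)
            for i, s in enumerate(starts)
        ]
        contigs = assemble_multi_k(
            reads, k_list=[31], min_count=1, compute_coverage=False, clean=False
        )
        if len(contigs) == 1 and contigs[0].seq == canonical_seq(seq):
            n_ok += 1
    return {"rate": n_ok / n_transcripts, "n": n_transcripts}


def end_to_end_recovery(seed: int) -> dict:
    """The mock-community parameter-recovery experiment.

    Three unrelated members across two orders, 200 genes, every expressed
    gene at >= 10x coverage, 1% substitution error, 10% rRNA; the
    reference database holds the community's true proteins.  Measures
    read-level functional precision/recall, genus-rank taxonomic
    precision, and the Pearson correlation between the true and the
    recovered KO expression profile.
    """
    spec, data = simulate.three_member_community(seed=seed)
    reads, truth = simulate.simulate_reads(spec, data)
    db = simulate.build_protein_db(data)
    result = pipeline.analyze(
        reads, list(data.rrna_refs.values()), db, data.tree,
        marker_db=data.marker_db,
    )
    mrna = truth[truth["molecule"] == "mRNA"]
    truth_ko = dict(zip(mrna["read_id"], mrna["ko"]))
    truth_tax = dict(zip(mrna["read_id"], mrna["taxid"]))
    pred_ko = {r: result.read_ko.get(r) for r in truth_ko}
    pred_tax = {r: result.read_taxid.get(r) for r in truth_tax}

    func = evaluation.functional_pr(truth_ko, pred_ko)
    tax = evaluation.taxonomic_pr(truth_tax, pred_tax, data.tree)
    truth_profile: dict[str, int] = {}
    for ko in truth_ko.values():
        if ko:
            truth_profile[ko] = truth_profile.get(ko, 0) + 1
    r = evaluation.profile_correlation(truth_profile, result.ko_profile())
    return {
        "functional_precision": func.precision,
        "functional_recall": func.recall,
        "genus_precision": tax["genus"].precision,
        "genus_recall": tax["genus"].recall,
        "order_precision": tax["order"].precision,
        "ko_pearson_r": r,
        "n_reads": len(truth_ko),
        "result": result,
        "data": data,
        "spec": spec,
        "truth": truth,
    }


def _two_order_community(seed: int, with_outsider: bool = False):
    lineages = [
        simulate._default_lineage(
            "Firmicutes", "Clostridia", "Clostridiales",
            "Clostridiaceae", "Clostridium", "C. one"),
        simulate._default_lineage(
            "Bacteroidetes", "Bacteroidia", "Bacteroidales",
            "Bacteroidaceae", "Bacteroides", "B. two"),
    ]
    members = [
        simulate.MemberSpec(
            name=f"m{i + 1}", lineage=lin, genome_length=12_000, n_genes=12,
            gene_len_range=(150, 450), n_marker_genes=6,
        )
        for i, lin in enumerate(lineages)
    ]
    if with_outsider:
        members.append(
            simulate.MemberSpec(
                name="outsider",
                lineage=simulate._default_lineage(
                    "Firmicutes", "Bacilli", "Lactobacillales",
                    "Lactobacillaceae", "Lactobacillus", "L. three"),
                genome_length=12_000, n_genes=8, gene_len_range=(150, 450),
                n_marker_genes=0,  # no detectable markers -> order missed
            )
        )
    spec = simulate.CommunitySpec(
        members=members,
        read_counts={m.name: 100 for m in members},
        seed=seed,
        n_marker_families=8,
    )
    return spec, simulate.generate_genomes(spec)


def two_step_equivalence(seed: int, n_communities: int = 20) -> dict:
    """Two-step vs one-step classification on communities fully inside
    the marker-derived search space, plus the outsider counterexample.

    When every member's order is recovered from the markers, restricting
    the database must not change any assignment.  A member contributing
    no markers leaves its order out of the space and its proteins
    unclassified.
    """
    n_proteins = 0
    n_agree = 0
    for i in range(n_communities):
        spec, data = _two_order_community(seed + i)
        db = simulate.build_protein_db(data)
        proteins = dict(db.seqs)
        two = taxonomy.classify_two_step(
            proteins, db, data.tree, data.marker_db
        )
        one = taxonomy.classify_one_step(proteins, db, data.tree)
        assert set(data.tree.rank_ancestor(m.taxid, "order")
                   for m in spec.members) == two.search_space
        for pid in proteins:
            n_proteins += 1
            n_agree += two.assignments[pid] == one[pid]

    spec, data = _two_order_community(seed, with_outsider=True)
    db = simulate.build_protein_db(data)
    proteins = dict(db.seqs)
    two = taxonomy.classify_two_step(proteins, db, data.tree, data.marker_db)
    outsider_order = data.tree.rank_ancestor(
        next(m for m in spec.members if m.name == "outsider").taxid, "order"
    )
    outsider_proteins = [
        pid for pid, taxid in db.taxids.items()
        if data.tree.rank_ancestor(taxid, "order") == outsider_order
    ]
    n_unclassified = sum(
        two.assignments[pid] is None for pid in outsider_proteins
    )
    return {
        "agreement_rate": n_agree / n_proteins,
        "n_proteins": n_proteins,
        "outsider_in_space": outsider_order in two.search_space,
        "outsider_unclassified_rate": n_unclassified / len(outsider_proteins),
        "n_outsider_proteins": len(outsider_proteins),
    }


def chimera_detection(seed: int, n_each: int = 20) -> dict:
    """Detector calibration on constructed contigs.

    Chimeras are 300+300 bp joins of two unrelated genomes; negatives are
    exact 600 bp substrings.  Reports the detection and false-flag rates.
    """
    spec, data = simulate.three_member_community(
        seed=seed, genes_per_member=(6, 6, 6)
    )
    genomes = {g.member: g.seq for g in data.genomes}
    rng = np.random.default_rng(seed + 1)
    names = sorted(genomes)
    from .assembler import Contig

    chimeras = []
    for i in range(n_each):
        a, b = rng.choice(names, size=2, replace=False)
        pa = int(rng.integers(0, len(genomes[a]) - 300))
        pb = int(rng.integers(0, len(genomes[b]) - 300))
        chimeras.append(
            Contig(f"chimera_{i}", genomes[a][pa:pa + 300] + genomes[b][pb:pb + 300])
        )
    cleans = []
    for i in range(n_each):
        a = str(rng.choice(names))
        pa = int(rng.integers(0, len(genomes[a]) - 600))
        cleans.append(Contig(f"clean_{i}", genomes[a][pa:pa + 600]))

    chim_classes = evaluation.classify_contigs(chimeras, genomes)
    clean_classes = evaluation.classify_contigs(cleans, genomes)
    return {
        "detection_rate": sum(c.cls == "chimeric" for c in chim_classes) / n_each,
        "false_flag_rate": sum(c.cls == "chimeric" for c in clean_classes) / n_each,
        "n_each": n_each,
    }


def coverage_threshold(
    seed: int,
    levels: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0, 5.0, 10.0),
    genes_per_level: int = 15,
) -> dict:
    """Assembled-gene fraction versus expected read coverage.

    One member expressing genes at fixed coverage levels (1% error); a
    gene counts as assembled when at least half of its k-mers appear in
    some contig.  The detected threshold is the lowest level where at
    least half the genes assemble.
    """
    n_genes = len(levels) * genes_per_level
    member = simulate.MemberSpec(
        name="solo",
        lineage=simulate._default_lineage(
            "Firmicutes", "Clostridia", "Clostridiales",
            "Ruminococcaceae", "Faecalibacterium", "F. solo"),
        genome_length=n_genes * 700,
        n_genes=n_genes,
        gene_len_range=(300, 450),
        n_marker_genes=0,
    )
    spec = simulate.CommunitySpec(
        members=[member], read_counts={"solo": 1}, seed=seed, error_rate=0.01
    )
    data = simulate.generate_genomes(spec)
    genes = data.genomes[0].genes
    weights = []
    for i, gene in enumerate(genes):
        cov = levels[i % len(levels)]
        weights.append(max(1.0, round(cov * gene.length / spec.read_length)))
    spec.abundance_profile = {"solo": weights}
    spec.read_counts = {"solo": int(sum(weights))}
    for gene, w in zip(genes, weights):
        gene.weight = w
    reads, _ = simulate.simulate_reads(spec, data)
    contigs = assemble_multi_k(reads, compute_coverage=False)
    assembled = evaluation.gene_assembled(data, contigs)
    cov = simulate.expected_coverage(spec, data)
    gene_cov = dict(zip(cov["gene_id"], cov["coverage"]))
    curve = evaluation.coverage_curve(gene_cov, assembled, bins=levels, q=0.5)
    return {"curve": curve, "n_genes": n_genes}


def filter_recovery(seed: int) -> dict:
    """Exact recovery of simulated rRNA and adapter fractions.

    Error-free two-member community with 10% rRNA reads and adapter
    read-through on 5% of mRNA reads; the filter cascade must remove
    exactly the simulated contaminants.
    """
    lineages = [
        simulate._default_lineage(
            "Firmicutes", "Clostridia", "Clostridiales",
            "Clostridiaceae", "Clostridium", "C. filt"),
        simulate._default_lineage(
            "Bacteroidetes", "Bacteroidia", "Bacteroidales",
            "Bacteroidaceae", "Bacteroides", "B. filt"),
    ]
    members = [
        simulate.MemberSpec(
            name=f"m{i + 1}", lineage=lin, genome_length=15_000, n_genes=15
        )
        for i, lin in enumerate(lineages)
    ]
    spec = simulate.CommunitySpec(
        members=members,
        read_counts={"m1": 1200, "m2": 600},
        seed=seed,
        error_rate=0.0,
        rrna_fraction=0.10,
        adapter_fraction=0.05,
        polya_fraction=0.05,
    )
    data = simulate.generate_genomes(spec)
    reads, truth = simulate.simulate_reads(spec, data)
    clean, report = preprocess.run_filters(
        reads, list(data.rrna_refs.values())
    )
    n_rrna_true = int((truth["molecule"] == "rRNA").sum())
    n_adapter_true = sum("artifact" in r.meta and r.meta["artifact"] == "adapter"
                         for r in reads)
    n_polya_true = sum(r.meta.get("artifact") == "polya" for r in reads)
    return {
        "report": report,
        "n_rrna_true": n_rrna_true,
        "n_adapter_true": n_adapter_true,
        "n_polya_true": n_polya_true,
        "n_reads": len(reads),
    }


def determinism_check(seed: int, workdir: str | Path) -> dict:
    """Byte-identity of two identically seeded full pipeline runs."""
    workdir = Path(workdir)
    spec, data = simulate.three_member_community(
        seed=seed, genes_per_member=(5, 5, 4)
    )
    reads, truth = simulate.simulate_reads(spec, data)
    dirs = []
    for tag in ("a", "b"):
        root = workdir / f"dataset_{tag}"
        simulate.write_community(data, reads, truth, root)
        out = workdir / f"run_{tag}"
        pipeline.run_pipeline(
            out,
            reads_path=root / "reads.fastq",
            rrna_path=root / "rrna.fasta",
            db_fasta=root / "proteins.faa",
            db_labels=root / "protein_labels.tsv",
            nodes_path=root / "nodes.tsv",
            names_path=root / "names.tsv",
            marker_fasta=root / "markers.faa",
            marker_labels=root / "marker_labels.tsv",
            truth_path=root / "truth.tsv",
        )
        dirs.append(out)
    a, b = dirs
    names = sorted(
        p.name for p in a.iterdir() if p.name != "manifest.json"
    )
    identical = all(
        filecmp.cmp(a / name, b / name, shallow=False) for name in names
    )
    return {"identical": identical, "n_files": len(names)}
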