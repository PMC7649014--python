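"""End-to-end orchestration: simulate/load -> curate -> align -> tree ->
clusters -> consensus phylogeny -> motifs -> report.

A run writes all intermediate artifacts under one output directory with
stable filenames; rerunning with the same configuration and seed reproduces
them byte-identically (no timestamps are embedded).  Every table carries
``#key=value`` provenance headers including a hash of the resolved
configuration; the ``manifest.tsv`` lists all artifacts with that hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .align import MultipleAlignment, consensus as consensus_of, progressive_msa
from .curation import CurationReport, curate
from .io import (
    read_fasta,
    write_alignment_fasta,
    write_clustal,
    write_fasta,
    write_newick,
)
from .motifs import BUILTIN_MOTIFS, digital_signature, find_egf_repeats, scan_motif
from .phylo import (
    Clustering,
    auto_threshold,
    cut_tree,
    msa_distance_matrix,
    specialized_phylogeny,
    upgma,
)
from .records import SequenceRecord
from .simulate import Benchmark, make_benchmark
from .tree import TreeNode


class PipelineError(RuntimeError):
    """A stage failure, prefixed with the stage name."""


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters with their defaults.

    Serializable to a flat ``key=value`` file; unknown keys are rejected on
    load so a typo cannot silently fall back to a default.
    """

    seed: int = 1
    members_per_clade: int = 6
    noise_fraction: float = 0.25
    duplicate_fraction: float = 0.125
    identity_threshold: float = 0.95
    min_norm_score: float = 0.3
    within_species: bool = True
    matrix: str = "gonnet250"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    distance_kind: str = "jc_protein"
    bootstrap_replicates: int = 100
    cut_height: Optional[float] = None  # None -> auto threshold
    consensus_gap_threshold: float = 0.5
    invariant_tau: float = 0.95
    class_tau: float = 0.95
    min_motif_len: int = 7
    max_wildcard_run: int = 2
    outgroup_patterns: str = "glp-1,lin-12"

    def to_items(self) -> list:
        return [(f.name, getattr(self, f.name)) for f in dataclasses.fields(self)]

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#config_hash={self.config_hash()}\n")
            for key, value in self.to_items():
                fh.write(f"{key}={'' if value is None else value}\n")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, _, raw = line.partition("=")
            key = key.strip()
            raw = raw.strip()
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            kwargs[key] = _parse_value(key, raw)
        return cls(**kwargs)

    def config_hash(self) -> str:
        text = "\n".join(f"{k}={v}" for k, v in self.to_items())
        return hashlib.sha1(text.encode()).hexdigest()[:12]

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)


def _parse_value(key: str, raw: str):
    if raw == "":
        return None
    if raw in {"True", "true"}:
        return True
    if raw in {"False", "false"}:
        return False
    for cast in (int, float):
        try:
            value = cast(raw)
        except ValueError:
            continue
        if cast is int and key in {"gap_open", "gap_extend", "cut_height",
                                   "noise_fraction", "duplicate_fraction"}:
            return float(value)
        return value
    return raw


@dataclass
class ClusterRow:
    name: str
    n_members: int
    organisms: tuple
    consensus_length: int
    motifs_found: str
    percent_of_clustered: float


@dataclass
class ClusterReport:
    rows: list
    n_retained: int
    n_outgroups: int
    min_length: int
    max_length: int

    def validate(self) -> None:
        clustered = self.n_retained - self.n_outgroups
        if sum(r.n_members for r in self.rows) != clustered:
            raise ValueError("cluster member counts do not sum to retained set")
        if any(r.n_members == 0 for r in self.rows):
            raise ValueError("empty cluster reported")


@dataclass
class PipelineResult:
    config: PipelineConfig
    out_dir: Path
    records: list
    curation_report: CurationReport
    retained: list
    outgroups: list
    msa: MultipleAlignment
    tree: TreeNode
    clustering: Clustering
    cluster_names: dict
    cluster_msas: dict
    consensus_records: list
    specialized_tree: Optional[TreeNode]
    signatures: dict
    report: ClusterReport
    benchmark: Optional[Benchmark] = None

    def path(self, name: str) -> Path:
        return self.out_dir / name


def _header(fh, config: PipelineConfig, **extra) -> None:
    fh.write(f"#config_hash={config.config_hash()}\n")
    for key, value in extra.items():
        fh.write(f"#{key}={value}\n")


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    input_fasta=None,
    references_fasta=None,
) -> PipelineResult:
    """Execute all stages; returns the in-memory result with artifact paths.

    Without ``input_fasta`` the synthetic benchmark configured by ``config``
    is generated (its clade ancestors serve as curation references); with a
    FASTA input, ``references_fasta`` must supply the reference exemplars.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_file(out / "config.txt")

    # -- stage: input -----------------------------------------------------
    benchmark = None
    try:
        if input_fasta is None:
            benchmark = make_benchmark(
                members_per_clade=config.members_per_clade,
                noise_fraction=config.noise_fraction,
                duplicate_fraction=config.duplicate_fraction,
                seed=config.seed,
            )
            records = benchmark.records
            references = benchmark.reference_records
            benchmark.write(out / "input.fasta", out / "truth.tsv")
        else:
            records = read_fasta(input_fasta)
            if references_fasta is None:
                raise ValueError("references_fasta is required for FASTA input")
            references = read_fasta(references_fasta)
    except Exception as exc:
        raise PipelineError(f"[input] {exc}") from exc

    # -- stage: curation --------------------------------------------------
    try:
        retained, report = curate(
            records,
            references,
            min_norm_score=config.min_norm_score,
            identity_threshold=config.identity_threshold,
            within_species=config.within_species,
            matrix=config.matrix,
            gap_open=config.gap_open,
            gap_extend=config.gap_extend,
        )
        if not retained:
            raise ValueError("no sequences retained after curation")
        write_fasta(retained, out / "curated.fasta")
        with open(out / "rejections.tsv", "w") as fh:
            _header(fh, config, stage="curation")
            fh.write("id\tstage\treason\n")
            for r in report.rejections:
                fh.write(f"{r.record_id}\t{r.stage}\t{r.reason}\n")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"[curate] {exc}") from exc

    # -- stage: outgroup split -------------------------------------------
    patterns = [
        p.strip().lower()
        for p in config.outgroup_patterns.split(",")
        if p.strip()
    ]
    outgroups = [
        r for r in retained
        if any(p in r.description.lower() for p in patterns)
    ]
    core = [r for r in retained if r not in outgroups]
    if len(core) < 2:
        raise PipelineError("[align] fewer than 2 non-outgroup sequences retained")

    # -- stage: alignment -------------------------------------------------
    try:
        msa = progressive_msa(
            core,
            matrix=config.matrix,
            gap_open=config.gap_open,
            gap_extend=config.gap_extend,
        )
        write_alignment_fasta(msa, out / "msa.afa")
        write_clustal(msa, out / "msa.clustal")
    except Exception as exc:
        raise PipelineError(f"[align] {exc}") from exc

    # -- stage: tree + clusters ------------------------------------------
    try:
        dm = msa_distance_matrix(msa, kind=config.distance_kind)
        with open(out / "distances.tsv", "w") as fh:
            _header(fh, config, kind=dm.kind)
            fh.write("label\t" + "\t".join(dm.labels) + "\n")
            for label, row in zip(dm.labels, dm.values):
                fh.write(
                    label + "\t" + "\t".join(format(v, ".10g") for v in row) + "\n"
                )
        tree = upgma(dm)
        write_newick(tree, out / "tree.nwk")
        if config.cut_height is not None:
            height = config.cut_height
        elif msa.n_rows >= 3:
            height = auto_threshold(tree)
        else:
            height = float(tree.height or 0.0) + 1.0
        clustering = cut_tree(tree, height)
    except Exception as exc:
        raise PipelineError(f"[tree] {exc}") from exc

    # name clusters by decreasing size, ties by first member id
    ordered = sorted(
        clustering.clusters, key=lambda m: (-len(m), m[0])
    )
    cluster_names = {f"C{k + 1}": members for k, members in enumerate(ordered)}
    with open(out / "clusters.tsv", "w") as fh:
        _header(fh, config, threshold=format(height, ".10g"),
                n_clusters=len(ordered))
        fh.write("cluster\tmember\n")
        for name, members in cluster_names.items():
            for m in members:
                fh.write(f"{name}\t{m}\n")

    # -- stage: consensus + specialized phylogeny ------------------------
    try:
        cluster_msas = {
            name: msa.subset(members) for name, members in cluster_names.items()
        }
        consensus_records = [
            SequenceRecord(
                id=name,
                residues=consensus_of(sub, config.consensus_gap_threshold),
                description=f"consensus of {sub.n_rows} members",
            )
            for name, sub in cluster_msas.items()
        ]
        write_fasta(consensus_records, out / "consensus.fasta")
        specialized = None
        if len(cluster_msas) >= 2:
            specialized = specialized_phylogeny(
                cluster_msas,
                outgroups,
                n_replicates=config.bootstrap_replicates,
                seed=config.seed,
                gap_rule_threshold=config.consensus_gap_threshold,
                matrix=config.matrix,
                gap_open=config.gap_open,
                gap_extend=config.gap_extend,
            )
            write_newick(specialized, out / "specialized_tree.nwk",
                         with_supports=True)
    except Exception as exc:
        raise PipelineError(f"[consensus] {exc}") from exc

    # -- stage: motifs ----------------------------------------------------
    try:
        signatures: dict[str, str] = {}
        motif_counts: dict[str, dict] = {}
        with open(out / "motifs.tsv", "w") as fh:
            _header(fh, config)
            fh.write("sequence\tpattern\tstart\tend\tmatch\n")
            for rec in consensus_records:
                counts: dict[str, int] = {}
                for label, pattern in BUILTIN_MOTIFS.items():
                    for hit in scan_motif(rec, pattern):
                        counts[label] = counts.get(label, 0) + 1
                        fh.write(
                            f"{rec.id}\t{label}\t{hit.start_1based}\t"
                            f"{hit.end_1based}\t{hit.match}\n"
                        )
                motif_counts[rec.id] = counts
                signatures[rec.id] = digital_signature(rec)
        with open(out / "signatures.tsv", "w") as fh:
            _header(fh, config)
            fh.write("sequence\tn_egf_repeats\tdigital_signature\n")
            for rec in consensus_records:
                sig = signatures[rec.id]
                fh.write(f"{rec.id}\t{len(sig)}\t{sig}\n")
    except Exception as exc:
        raise PipelineError(f"[motifs] {exc}") from exc

    # -- stage: report ----------------------------------------------------
    try:
        lengths = [r.length for r in retained]
        clustered = len(core)
        rows = []
        by_id = {r.id: r for r in retained}
        for name, members in cluster_names.items():
            cons = next(c for c in consensus_records if c.id == name)
            found = sorted(
                label for label, n in motif_counts.get(name, {}).items() if n
            )
            rows.append(
                ClusterRow(
                    name=name,
                    n_members=len(members),
                    organisms=tuple(
                        sorted({by_id[m].organism for m in members if by_id[m].organism})
                    ),
                    consensus_length=cons.length,
                    motifs_found=",".join(found),
                    percent_of_clustered=round(100.0 * len(members) / clustered, 1),
                )
            )
        cluster_report = ClusterReport(
            rows=rows,
            n_retained=len(retained),
            n_outgroups=len(outgroups),
            min_length=min(lengths),
            max_length=max(lengths),
        )
        cluster_report.validate()
        with open(out / "report.tsv", "w") as fh:
            _header(fh, config, n_retained=len(retained),
                    n_outgroups=len(outgroups),
                    min_length=min(lengths), max_length=max(lengths))
            fh.write(
                "cluster\tn_members\tpercent\tconsensus_length\tmotifs\torganisms\n"
            )
            for row in rows:
                fh.write(
                    f"{row.name}\t{row.n_members}\t{row.percent_of_clustered}\t"
                    f"{row.consensus_length}\t{row.motifs_found}\t"
                    f"{';'.join(row.organisms)}\n"
                )
    except Exception as exc:
        raise PipelineError(f"[report] {exc}") from exc

    artifacts = sorted(p.name for p in out.iterdir() if p.is_file())
    with open(out / "manifest.tsv", "w") as fh:
        _header(fh, config, seed=config.seed)
        fh.write("artifact\n")
        for name in artifacts:
            if name != "manifest.tsv":
                fh.write(name + "\n")

    return PipelineResult(
        config=config,
        out_dir=out,
        records=records,
        curation_report=report,
        retained=retained,
        outgroups=outgroups,
        msa=msa,
        tree=tree,
        clustering=clustering,
        cluster_names=cluster_names,
        cluster_msas=cluster_msas,
        consensus_records=consensus_records,
        specialized_tree=specialized,
        signatures=signatures,
        report=cluster_report,
        benchmark=benchmark,
    )


def summarize(result: PipelineResult) -> str:
    """Human-readable run summary (also written as summary.txt)."""
    rep = result.report
    lines = [
        f"retained {rep.n_retained} sequences "
        f"({rep.n_outgroups} outgroup homologs held out of clustering)",
        f"sequence length range: {rep.min_length}-{rep.max_length} aa",
        f"clusters at threshold {result.clustering.threshold:.4g}: "
        f"{len(rep.rows)}",
    ]
    for row in rep.rows:
        lines.append(
            f"  {row.name}: {row.n_members} members ({row.percent_of_clustered}%), "
            f"consensus {row.consensus_length} aa, motifs [{row.motifs_found}], "
            f"organisms: {', '.join(row.organisms) or '-'}"
        )
    total = sum(row.percent_of_clustered for row in rep.rows)
    lines.append(f"cluster percentages sum to {total:.1f}")
    text = "\n".join(lines)
    with open(result.out_dir / "summary.txt", "w") as fh:
        fh.write(text + "\n")
    return text
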