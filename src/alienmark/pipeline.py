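"""End-to-end marker-discovery pipeline.

Composes the stages into the discovery funnel: digest and size-select each
cultivar, cluster loci, drop everything homologous to the host, intersect
across cultivars, design PCR primers, screen for universality, place
markers on chromosomes and arms against the addition-line panel, verify on
a second panel, and convert arm-assigned markers into validated co-dominant
KASP assays.  Record counts after every filter are logged and returned, so
a run reads like the funnel it is.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
import yaml

from alienmark import assign as assign_mod
from alienmark.assign import (
    STATUS_ARM,
    STATUS_CHROMOSOME,
    ArmAssignment,
    assign_arm,
    assign_chromosome,
    screen_universal,
    validate_universality,
)
from alienmark.digestion import SLAFLocus, cluster_loci, digest, size_select
from alienmark.genome import Genome, write_fasta
from alienmark.kasp import (
    KASPAssay,
    KaspPrimerConfig,
    KaspValidationReport,
    anchor_to_scaffolds,
    build_kasp_assay,
    call_diagnostic_snps,
    insilico_kasp_genotype,
    validate_kasp_table,
    write_kasp_table,
)
from alienmark.genotyping import CallerConfig
from alienmark.panel import LinePanel
from alienmark.primers import (
    AmplificationMatrix,
    MismatchPolicy,
    PCRMarker,
    PrimerConfig,
    SiteCache,
    amplification_matrix,
    design_primers,
    insilico_pcr,
    markers_to_frame,
)
from alienmark.simulate import (
    SimulationConfig,
    TruthTable,
    build_panel,
    make_scaffolds,
    simulate_genomes,
)
from alienmark.specificity import (
    ConservedLocus,
    filter_specific,
    homology_reports,
    intersect_cultivars,
    reports_to_frame,
)

logger = logging.getLogger("alienmark")


@dataclass
class PipelineConfig:
    """All stage thresholds in one place, YAML round-trippable.

    Defaults mirror the published protocol: RsaI digestion, a 464-494 bp
    selection window, loci clustered at >90% identity, host homology below
    50% for specificity, conservation at 90%, 40-120 bp SNP flanks.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    site: str = "GTAC"
    cut_offset: int = 2
    size_window: Tuple[int, int] = (464, 494)
    cluster_identity: float = 0.90
    specificity_threshold: float = 0.50
    conservation_threshold: float = 0.90
    flank_range: Tuple[int, int] = (40, 120)
    consistency_threshold: float = 0.90
    anchor_best_identity: float = 0.95
    anchor_second_identity: float = 0.90
    anchor_expansion: int = 5000
    max_markers: int = 160
    kasp_per_arm: int = 1
    size_tolerance: float = 0.10
    primer: PrimerConfig = field(default_factory=PrimerConfig)
    kasp_primer: KaspPrimerConfig = field(default_factory=KaspPrimerConfig)
    policy: MismatchPolicy = field(default_factory=MismatchPolicy)
    caller: CallerConfig = field(default_factory=CallerConfig)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        for key, sub in (
            ("simulation", SimulationConfig),
            ("primer", PrimerConfig),
            ("kasp_primer", KaspPrimerConfig),
            ("policy", MismatchPolicy),
            ("caller", CallerConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**_tuplify(sub, kwargs[key]))
        return cls(**_tuplify(cls, kwargs))


def _tuplify(dc_type, kwargs: dict) -> dict:
    """YAML lists back to tuples where the dataclass declares tuples."""
    out = dict(kwargs)
    for f in dataclasses.fields(dc_type):
        if f.name in out and isinstance(out[f.name], list):
            out[f.name] = tuple(out[f.name])
    return out


@dataclass
class PipelineResult:
    host: Genome
    cultivars: List[Genome]
    truth: TruthTable
    loci_by_cultivar: Dict[str, List[SLAFLocus]]
    specific_by_cultivar: Dict[str, List[SLAFLocus]]
    conserved: List[ConservedLocus]
    markers: List[PCRMarker]
    universal_ids: List[str]
    panel: LinePanel
    line_genomes: Dict[str, Genome]
    matrix: AmplificationMatrix
    assignments: Dict[str, ArmAssignment]
    second_panel_validated: Dict[str, bool]
    assays: List[KASPAssay]
    kasp_report: KaspValidationReport
    funnel: Dict[str, int]
    outdir: Optional[Path] = None

    def marker_by_id(self, marker_id: str) -> PCRMarker:
        return next(m for m in self.markers if m.marker_id == marker_id)

    def conserved_by_id(self, locus_id: str) -> ConservedLocus:
        return next(c for c in self.conserved if c.locus_id == locus_id)


@contextmanager
def _stage(name: str):
    logger.info("stage %s: start", name)
    try:
        yield
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc


def expected_panel_genotype(line_content: Tuple[str, ...], arm_id: str, role: str) -> str:
    """What a correct arm-specific KASP assay should call on a panel line."""
    if role == "alien_control":
        return "A1A1"
    chrom = arm_id[:-1]
    carries = any(c == arm_id or c == chrom for c in line_content)
    return "A1A2" if carries else "A2A2"


def run_pipeline(config: PipelineConfig, outdir: Optional[Path | str] = None) -> PipelineResult:
    """Run the whole discovery funnel on simulated genomes.

    With *outdir* set, every stage product is written (FASTA/TSV), along
    with a config snapshot and a manifest of output checksums; reruns with
    the same config reproduce the manifest bit-exactly.
    """
    funnel: Dict[str, int] = {}

    with _stage("simulate"):
        host, cultivars, truth = simulate_genomes(config.simulation)
    discovery, donor = cultivars[:-1], cultivars[-1]

    loci_by_cultivar: Dict[str, List[SLAFLocus]] = {}
    with _stage("slaf_extraction"):
        n_frag = n_sel = 0
        for cult in discovery:
            frags = digest(cult, config.site, config.cut_offset)
            kept = size_select(frags, config.size_window)
            n_frag += len(frags)
            n_sel += len(kept)
            loci_by_cultivar[cult.id] = cluster_loci(kept, cult.id, config.cluster_identity)
        funnel["fragments"] = n_frag
        funnel["fragments_in_window"] = n_sel
        funnel["loci"] = sum(len(v) for v in loci_by_cultivar.values())
        logger.info(
            "digested %d fragments, %d in window, %d loci",
            n_frag, n_sel, funnel["loci"],
        )

    specific_by_cultivar: Dict[str, List[SLAFLocus]] = {}
    homology_frames = []
    with _stage("specificity"):
        for cult_id, loci in loci_by_cultivar.items():
            reports = homology_reports(loci, host, config.specificity_threshold)
            frame = reports_to_frame(reports)
            frame.insert(1, "cultivar", cult_id)
            homology_frames.append(frame)
            specific_by_cultivar[cult_id] = [
                locus for locus, rep in zip(loci, reports) if rep.is_specific
            ]
        funnel["specific_loci"] = sum(len(v) for v in specific_by_cultivar.values())
        conserved = intersect_cultivars(specific_by_cultivar, config.conservation_threshold)
        funnel["conserved_specific"] = len(conserved)
        logger.info(
            "%d specific loci, %d conserved across all cultivars",
            funnel["specific_loci"], funnel["conserved_specific"],
        )

    markers: List[PCRMarker] = []
    with _stage("pcr_design"):
        for locus in conserved[: config.max_markers]:
            pairs = design_primers(locus, config.primer)
            if pairs:
                markers.append(
                    PCRMarker(
                        marker_id=f"M{len(markers) + 1:04d}",
                        pair=pairs[0],
                        source=locus.locus_id,
                    )
                )
        funnel["markers_designed"] = len(markers)

    cache = SiteCache()

    def amplifies(marker: PCRMarker, genome: Genome) -> bool:
        amps = insilico_pcr(marker.pair, genome, config.policy, cache)
        tol = config.size_tolerance * marker.expected_size
        return any(abs(a.size - marker.expected_size) <= tol for a in amps)

    with _stage("universality_screen"):
        universal_ids = []
        cultivar_names = [c.id for c in discovery]
        for marker in markers:
            pattern = {c.id: amplifies(marker, c) for c in discovery}
            pattern[host.id] = amplifies(marker, host)
            if screen_universal(pattern, cultivar_names, host.id):
                universal_ids.append(marker.marker_id)
        funnel["universal_markers"] = len(universal_ids)
        logger.info("%d universal alien-specific markers", len(universal_ids))

    with _stage("panel_matrix"):
        panel, line_genomes = build_panel(host, donor)
        universal_markers = [m for m in markers if m.marker_id in set(universal_ids)]
        matrix = amplification_matrix(
            universal_markers, panel, line_genomes, config.policy, config.size_tolerance
        )

    assignments: Dict[str, ArmAssignment] = {}
    with _stage("arm_assignment"):
        for marker in universal_markers:
            row = matrix.row(marker.marker_id)
            a = assign_chromosome(marker.marker_id, row, panel)
            if a.status == STATUS_CHROMOSOME:
                a = assign_arm(a, row, panel)
            assignments[marker.marker_id] = a
        funnel["chromosome_assigned"] = sum(
            1 for a in assignments.values() if a.status in (STATUS_CHROMOSOME, STATUS_ARM)
        )
        funnel["arm_assigned"] = sum(
            1 for a in assignments.values() if a.status == STATUS_ARM
        )
        logger.info(
            "%d chromosome-assigned (%d to arms)",
            funnel["chromosome_assigned"], funnel["arm_assigned"],
        )

    second_validated: Dict[str, bool] = {}
    with _stage("second_panel"):
        second_panel, second_genomes = build_panel(host, discovery[0])
        second_panel = LinePanel(
            lines=second_panel.lines, host_id=host.id, alien_id=discovery[0].id
        )
        placed = [
            m for m in universal_markers
            if assignments[m.marker_id].status in (STATUS_CHROMOSOME, STATUS_ARM)
        ]
        matrix2 = amplification_matrix(
            placed, second_panel, second_genomes, config.policy, config.size_tolerance
        )
        for marker in placed:
            second_validated[marker.marker_id] = validate_universality(
                assignments[marker.marker_id], matrix2.row(marker.marker_id), second_panel
            )
        funnel["second_panel_validated"] = sum(second_validated.values())

    assays: List[KASPAssay] = []
    with _stage("kasp_design"):
        scaffolds = make_scaffolds(donor, config.simulation.scaffold_piece_length)
        conserved_by_id = {c.locus_id: c for c in conserved}
        per_arm: Dict[str, int] = {}
        for marker in universal_markers:
            a = assignments[marker.marker_id]
            if a.status != STATUS_ARM or not second_validated.get(marker.marker_id):
                continue
            arm_id = a.arm_id
            if per_arm.get(arm_id, 0) >= config.kasp_per_arm:
                continue
            locus = conserved_by_id[marker.source]
            anchor = anchor_to_scaffolds(
                locus,
                scaffolds,
                config.anchor_best_identity,
                config.anchor_second_identity,
                expansion=config.anchor_expansion,
            )
            if not anchor.unique or not anchor.expanded_sequence:
                continue
            snps = call_diagnostic_snps(
                anchor.expanded_sequence,
                host,
                config.flank_range,
                config.consistency_threshold,
                locus_id=locus.locus_id,
            )
            for snp in snps:
                try:
                    assay = build_kasp_assay(
                        snp, arm_id, config.kasp_primer,
                        assay_id=f"K{marker.marker_id}",
                    )
                except ValueError:
                    continue
                ok = all(
                    insilico_kasp_genotype(assay, line_genomes[line.line_id], cache=cache)
                    == expected_panel_genotype(line.content, arm_id, line.role)
                    for line in panel.lines
                )
                if ok:
                    assays.append(assay)
                    per_arm[arm_id] = per_arm.get(arm_id, 0) + 1
                    break
        funnel["kasp_assays"] = len(assays)
        kasp_report = validate_kasp_table(assays)
        funnel["kasp_valid"] = kasp_report.n_valid
        funnel["kasp_arms"] = kasp_report.n_arms
        logger.info(
            "%d KASP assays built (%d valid, %d arms)",
            len(assays), kasp_report.n_valid, kasp_report.n_arms,
        )

    result = PipelineResult(
        host=host,
        cultivars=cultivars,
        truth=truth,
        loci_by_cultivar=loci_by_cultivar,
        specific_by_cultivar=specific_by_cultivar,
        conserved=conserved,
        markers=markers,
        universal_ids=universal_ids,
        panel=panel,
        line_genomes=line_genomes,
        matrix=matrix,
        assignments=assignments,
        second_panel_validated=second_validated,
        assays=assays,
        kasp_report=kasp_report,
        funnel=funnel,
    )

    if outdir is not None:
        with _stage("write_outputs"):
            result.outdir = _write_outputs(
                Path(outdir), config, result, homology_frames
            )
    return result


# ---------------------------------------------------------------------------
# output writing


def _loci_frame(loci_by_cultivar: Dict[str, List[SLAFLocus]]) -> pd.DataFrame:
    rows = []
    for cult, loci in loci_by_cultivar.items():
        for locus in loci:
            rep = locus.members[0]
            rows.append(
                (locus.locus_id, cult, rep.contig, rep.start, rep.end, locus.size, locus.n_members)
            )
    return pd.DataFrame(
        rows,
        columns=["locus_id", "cultivar", "contig", "start", "end", "size", "n_members"],
    )


def _write_outputs(
    outdir: Path,
    config: PipelineConfig,
    result: PipelineResult,
    homology_frames: List[pd.DataFrame],
) -> Path:
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    write_fasta(result.host, outdir / "host.fa")
    for cult in result.cultivars:
        write_fasta(cult, outdir / f"{cult.id}.fa")
    result.truth.to_tsv(outdir / "truth.tsv")
    result.panel.to_tsv(outdir / "panel.tsv")
    _loci_frame(result.loci_by_cultivar).to_csv(outdir / "loci.tsv", sep="\t", index=False)
    if homology_frames:
        pd.concat(homology_frames, ignore_index=True).to_csv(
            outdir / "homology.tsv", sep="\t", index=False
        )
    with open(outdir / "conserved.fa", "w") as fh:
        for locus in result.conserved:
            fh.write(f">{locus.locus_id}\n{locus.sequence}\n")
    arms = {
        m: (a.arm_id or a.chromosome or "")
        for m, a in result.assignments.items()
        if a.status in (STATUS_CHROMOSOME, STATUS_ARM)
    }
    markers_to_frame(result.markers, arms).to_csv(
        outdir / "markers.tsv", sep="\t", index=False
    )
    result.matrix.to_tsv(outdir / "matrix.tsv")
    pd.DataFrame(
        {
            "marker_id": list(result.assignments),
            "status": [a.status for a in result.assignments.values()],
            "chromosome": [a.chromosome or "" for a in result.assignments.values()],
            "arm": [a.arm or "" for a in result.assignments.values()],
            "reason": [a.reason for a in result.assignments.values()],
            "second_panel_ok": [
                int(result.second_panel_validated.get(m, False))
                for m in result.assignments
            ],
        }
    ).to_csv(outdir / "assignments.tsv", sep="\t", index=False)
    write_kasp_table(result.assays, outdir / "kasp_table.tsv")

    checksums = {}
    for path in sorted(outdir.iterdir()):
        if path.name == "manifest.json" or path.is_dir():
            continue
        checksums[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest = {
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(dataclasses.asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "funnel": result.funnel,
        "checksums": checksums,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir
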