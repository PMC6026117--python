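"""End-to-end orchestration and the synthetic paired-sample demonstration.

``run_demo`` simulates paired calculus-like and dentin-like metagenomes
(plus an undamaged extraction blank), runs every analysis stage, and emits
a report asserting the qualitative contrasts the pipeline is built to
detect:

  1. host reads are shorter than the bulk (microbial) DNA in every
     calculus-like sample;
  2. calculus-like communities cluster: each is closer (Bray-Curtis) to
     other calculus-like samples than to its own paired dentin-like sample;
  3. a GC-vs-length shift onset appears under GC-biased fragment survival
     and not under GC-independent survival;
  4. undamaged contaminant reads fail the damage criterion of host-read
     authentication.

Every stage derives its seed from the global seed by stable hashing of the
stage name, so stages can be rerun independently yet reproducibly, and all
output tables carry a ``# seed=... config=...`` provenance line.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import authfilter, community, damage, fraglen, gcshift
from .io_qc import QCConfig, qc_filter, read_fastq, write_fastq, write_table
from .sim_reads import (
    BriggsParams,
    LengthModel,
    ReferenceGenome,
    SampleConfig,
    SurvivalModel,
    draw_fragments,
    fragment_gc_counts,
    perfect_alignments,
    random_genome,
    read_truth,
    simulate_sample,
    survival_probability,
)

logger = logging.getLogger("paleoprof")


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 derived from the global seed."""
    digest = hashlib.blake2b(f"{global_seed}:{stage}".encode(), digest_size=4)
    return int.from_bytes(digest.digest(), "big") % (2**31)


@dataclass(frozen=True)
class PipelineConfig:
    """Global knobs for the synthetic demonstration pipeline."""

    seed: int = 1
    out_dir: str = "paleoprof_demo"
    n_individuals: int = 3
    reads_per_sample: int = 20000
    blank_reads: int = 4000
    gc_experiment_reads: int = 60000
    qc: QCConfig = field(default_factory=QCConfig)
    subsample: fraglen.SubsampleConfig = field(default_factory=fraglen.SubsampleConfig)
    gcshift: gcshift.GCShiftConfig = field(default_factory=gcshift.GCShiftConfig)

    def config_hash(self) -> str:
        payload = repr(sorted(self.__dict__.items(), key=lambda kv: kv[0]))
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def meta(self) -> dict:
        return {"seed": self.seed, "config": self.config_hash()}


def parse_config_file(path: str | Path) -> PipelineConfig:
    """Flat key=value config file -> PipelineConfig (unknown keys rejected)."""
    values: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
        key, _, value = line.partition("=")
        values[key.strip()] = value.strip()
    kwargs: dict = {}
    int_keys = {
        "seed", "n_individuals", "reads_per_sample", "blank_reads",
        "gc_experiment_reads",
    }
    for key, value in values.items():
        if key in int_keys:
            kwargs[key] = int(value)
        elif key == "out_dir":
            kwargs[key] = value
        elif key in ("min_base_quality", "min_length"):
            kwargs.setdefault("qc_kwargs", {})[key] = (
                float(value) if key == "min_base_quality" else int(value)
            )
        else:
            raise ValueError(f"{path}: unknown config key {key!r}")
    qc_kwargs = kwargs.pop("qc_kwargs", None)
    if qc_kwargs:
        kwargs["qc"] = QCConfig(**qc_kwargs)
    return PipelineConfig(**kwargs)


# ---------------------------------------------------------------------------
# The stated synthetic world
# ---------------------------------------------------------------------------

HOST_TAXON = "Homo_sapiens_synth"

# (taxon_id, genomic GC, gram, s_layer, gc_class, source path)
_PANEL = [
    (HOST_TAXON, 0.41, "NA", "NA", "medium", None),
    ("Methanobrevibacter_oralis_synth", 0.28, "positive", "present", "low",
     "human microbiome>human oral"),
    ("Tannerella_forsythia_synth", 0.47, "negative", "present", "medium",
     "human microbiome>human oral>pathobiont"),
    ("Actinomyces_dentalis_synth", 0.66, "positive", "absent", "high",
     "human microbiome>human oral"),
    ("Streptomyces_soil_synth", 0.70, "positive", "absent", "high",
     "environmental"),
    ("Arthrobacter_soil_synth", 0.63, "positive", "absent", "high",
     "environmental"),
    ("Pseudomonas_soil_synth", 0.60, "negative", "absent", "high",
     "environmental"),
    ("Uncultured_soil_bacterium_synth", 0.55, "NA", "NA", "medium",
     "environmental>uncultured environmental"),
]

GENOME_LENGTH = 60000

# Compositions mirror well-preserved oral biofilm vs contaminated dentin:
# calculus-like samples are ~90% oral taxa; dentin-like samples are ~85%
# environmental, spread across taxa — postmortem contamination is
# taxonomically diffuse, which is what drives dentin's higher alpha
# diversity.
CALCULUS_ABUNDANCES = {
    HOST_TAXON: 0.05,
    "Methanobrevibacter_oralis_synth": 0.30,
    "Tannerella_forsythia_synth": 0.30,
    "Actinomyces_dentalis_synth": 0.30,
    "Streptomyces_soil_synth": 0.02,
    "Arthrobacter_soil_synth": 0.01,
    "Pseudomonas_soil_synth": 0.01,
    "Uncultured_soil_bacterium_synth": 0.01,
}
DENTIN_ABUNDANCES = {
    HOST_TAXON: 0.10,
    "Methanobrevibacter_oralis_synth": 0.02,
    "Tannerella_forsythia_synth": 0.02,
    "Actinomyces_dentalis_synth": 0.01,
    "Streptomyces_soil_synth": 0.25,
    "Arthrobacter_soil_synth": 0.22,
    "Pseudomonas_soil_synth": 0.20,
    "Uncultured_soil_bacterium_synth": 0.18,
}

# Microbial fragments: median 70 bp; host fragments 15 bp shorter (median
# 55 bp), reproducing the observed displacement of endogenous host DNA.
MICROBIAL_LENGTHS = LengthModel(location=70.0, scale=0.35, min_len=20, max_len=250)
HOST_LENGTHS = MICROBIAL_LENGTHS.shifted(-15.0)

CALCULUS_DAMAGE = BriggsParams(lam=0.30, delta_d=0.40, delta_s=0.01)
DENTIN_DAMAGE = BriggsParams(lam=0.25, delta_d=0.48, delta_s=0.01)
NO_DAMAGE = BriggsParams(lam=0.30, delta_d=0.0, delta_s=0.0)

CONTAMINANT_FRACTION = 0.03


@dataclass
class World:
    """Reference genomes and species metadata of the synthetic panel."""

    references: dict[str, ReferenceGenome]
    metadata: pd.DataFrame


def build_world(config: PipelineConfig) -> World:
    """Deterministically regenerate the panel genomes and their metadata."""
    refs: dict[str, ReferenceGenome] = {}
    rows = []
    for taxon, gc, gram, s_layer, gc_class, source in _PANEL:
        seed = stage_seed(config.seed, f"genome:{taxon}")
        refs[taxon] = random_genome(taxon, GENOME_LENGTH, gc, seed)
        rows.append(
            {
                "taxon_id": taxon,
                "gram": gram,
                "s_layer": s_layer,
                "genomic_gc": refs[taxon].genomic_gc,
                "gc_class": gc_class,
                "source_path": source,
            }
        )
    metadata = pd.DataFrame(rows).set_index("taxon_id")
    return World(references=refs, metadata=metadata)


def sample_names(config: PipelineConfig) -> list[str]:
    names = []
    for i in range(1, config.n_individuals + 1):
        names.append(f"IND{i}_calculus")
        names.append(f"IND{i}_dentin")
    names.append("BLANK")
    return names


def _sample_configs(config: PipelineConfig, world: World) -> dict[str, list[SampleConfig]]:
    """Per sample, a microbial config plus a shorter-fragment host config.

    Host reads get their own config because their length model is displaced;
    the two runs share the sample id and are merged on output.
    """
    out: dict[str, list[SampleConfig]] = {}
    for name in sample_names(config):
        seed = stage_seed(config.seed, f"simulate:{name}")
        if name == "BLANK":
            # extraction blank: modern (undamaged) human contamination only
            out[name] = [
                SampleConfig(
                    taxa=((world.references[HOST_TAXON], 1.0),),
                    n_reads=config.blank_reads,
                    length_model=MICROBIAL_LENGTHS,
                    damage=CALCULUS_DAMAGE,
                    contaminant_fraction=1.0,
                    seed=seed,
                    sample_id=name,
                )
            ]
            continue
        abundances = (
            CALCULUS_ABUNDANCES if name.endswith("calculus") else DENTIN_ABUNDANCES
        )
        damage_params = (
            CALCULUS_DAMAGE if name.endswith("calculus") else DENTIN_DAMAGE
        )
        host_share = abundances[HOST_TAXON]
        n_host = int(round(config.reads_per_sample * host_share))
        microbial = {t: a for t, a in abundances.items() if t != HOST_TAXON}
        total = sum(microbial.values())
        taxa = tuple(
            (world.references[t], a / total) for t, a in sorted(microbial.items())
        )
        out[name] = [
            SampleConfig(
                taxa=taxa,
                n_reads=config.reads_per_sample - n_host,
                length_model=MICROBIAL_LENGTHS,
                damage=damage_params,
                contaminant_fraction=CONTAMINANT_FRACTION,
                seed=seed,
                sample_id=name,
            ),
            SampleConfig(
                taxa=((world.references[HOST_TAXON], 1.0),),
                n_reads=n_host,
                length_model=HOST_LENGTHS,
                damage=damage_params,
                contaminant_fraction=CONTAMINANT_FRACTION,
                seed=stage_seed(config.seed, f"simulate-host:{name}"),
                sample_id=name,
            ),
        ]
    return out


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _sim_dir(config: PipelineConfig) -> Path:
    return Path(config.out_dir) / "sim"


def stage_simulate(config: PipelineConfig) -> dict:
    """Simulate every sample; writes FASTQ + truth TSV per sample."""
    world = build_world(config)
    sim_dir = _sim_dir(config)
    sim_dir.mkdir(parents=True, exist_ok=True)
    counts = {}
    for name, cfgs in _sample_configs(config, world).items():
        reads, truths = [], []
        for cfg in cfgs:
            r, t = simulate_sample(
                cfg, sim_dir / f"{name}.part.fastq", sim_dir / f"{name}.part.truth.tsv"
            )
            reads.extend(r)
            truths.extend(t)
        from .sim_reads import write_truth

        write_fastq(reads, sim_dir / f"{name}.fastq")
        write_truth(truths, sim_dir / f"{name}.truth.tsv")
        (sim_dir / f"{name}.part.fastq").unlink()
        (sim_dir / f"{name}.part.truth.tsv").unlink()
        counts[name] = len(reads)
        logger.info("simulate: %s -> %d reads", name, len(reads))
    return {"reads_per_sample": counts}


def _load_sample(config: PipelineConfig, name: str):
    sim_dir = _sim_dir(config)
    fastq = sim_dir / f"{name}.fastq"
    truth = sim_dir / f"{name}.truth.tsv"
    if not fastq.exists() or not truth.exists():
        raise FileNotFoundError(
            f"missing simulated outputs for sample {name!r} under {sim_dir}; "
            "run the 'simulate' stage first"
        )
    reads = list(read_fastq(fastq, sample_id=name))
    truths = read_truth(truth)
    taxon_by_id = {t.read_id: t.taxon_id for t in truths}
    for read in reads:
        read.taxon_id = taxon_by_id.get(read.read_id)
    return reads, truths


def stage_qc(config: PipelineConfig) -> dict:
    """Length/quality filter each simulated sample; writes a QC tally table."""
    out_dir = Path(config.out_dir) / "qc"
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for name in sample_names(config):
        reads, _ = _load_sample(config, name)
        kept, dropped = qc_filter(reads, config.qc)
        write_fastq(kept, out_dir / f"{name}.fastq")
        rows.append(
            {
                "sample_id": name,
                "input": len(reads),
                "kept": len(kept),
                "dropped_length": dropped.get("length", 0),
                "dropped_quality": dropped.get("quality", 0),
            }
        )
        logger.info("qc: %s kept %d/%d", name, len(kept), len(reads))
    table = pd.DataFrame(rows).set_index("sample_id")
    write_table(table, out_dir / "qc_report.tsv", meta=config.meta())
    return {"qc": {r["sample_id"]: r["kept"] for r in rows}}


def _qc_lengths(config: PipelineConfig, name: str):
    """(host lengths, all lengths, non-host lengths) of QC-passing reads."""
    reads, _ = _load_sample(config, name)
    kept, _ = qc_filter(reads, config.qc)
    host = [r.length for r in kept if r.taxon_id == HOST_TAXON]
    non_host = [r.length for r in kept if r.taxon_id != HOST_TAXON]
    return host, [r.length for r in kept], non_host


def stage_fraglen(config: PipelineConfig) -> dict:
    """Median displacement of host reads and per-sample length summaries."""
    out_dir = Path(config.out_dir) / "fraglen"
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for name in sample_names(config):
        if name == "BLANK":
            continue
        host, overall, non_host = _qc_lengths(config, name)
        displacement = fraglen.median_displacement(host, overall)
        effect = fraglen.cohens_d(host, non_host)
        rows.append(
            {
                "sample_id": name,
                "material": name.split("_")[-1],
                "n_host": len(host),
                "median_host": float(np.median(host)),
                "median_overall": float(np.median(overall)),
                "host_displacement_bp": displacement,
                "cohens_d_host_vs_nonhost": effect,
            }
        )
    table = pd.DataFrame(rows).set_index("sample_id")
    write_table(table, out_dir / "host_displacement.tsv", meta=config.meta())
    calculus = table[table["material"] == "calculus"]
    host_shorter = bool((calculus["host_displacement_bp"] < 0).all())
    return {
        "host_shorter_in_all_calculus": host_shorter,
        "mean_calculus_displacement_bp": float(
            calculus["host_displacement_bp"].mean()
        ),
    }


def stage_damage(config: PipelineConfig) -> dict:
    """Pooled misincorporation profile + overhang-model fit per sample."""
    world = build_world(config)
    out_dir = Path(config.out_dir) / "damage"
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    terminal = {}
    for name in sample_names(config):
        reads, truths = _load_sample(config, name)
        alignments = perfect_alignments(reads, truths, world.references)
        profile = damage.misincorporation_profile(alignments)
        profile.write(out_dir / f"{name}.profile.tsv", meta=config.meta())
        fit = damage.fit_briggs(profile)
        verdict = damage.damage_presence(profile)
        terminal[name] = float(profile.ct5[0])
        rows.append(
            {
                "sample_id": name,
                "ct5_pos1": float(profile.ct5[0]),
                "lam": fit.params.lam,
                "delta_d": fit.params.delta_d,
                "delta_s": fit.params.delta_s,
                "damage_status": verdict.status,
            }
        )
    table = pd.DataFrame(rows).set_index("sample_id")
    write_table(table, out_dir / "fits.tsv", meta=config.meta())
    dentin = [terminal[f"IND{i}_dentin"] for i in range(1, config.n_individuals + 1)]
    calculus = [
        terminal[f"IND{i}_calculus"] for i in range(1, config.n_individuals + 1)
    ]
    paired = damage.compare_paired_damage(dentin, calculus)
    return {
        "blank_damage_status": table.loc["BLANK", "damage_status"],
        "dentin_vs_calculus_terminal_p": paired.pvalue,
    }


def simulate_survival_fragments(
    ref: ReferenceGenome,
    n: int,
    survival: SurvivalModel,
    length_model: LengthModel,
    seed,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw fragments, thin them by survival, return (lengths, gc fractions).

    A read-free shortcut for survival-bias experiments: GC content is taken
    from the reference interval, which equals the read's GC when no damage
    or sequencing error is simulated.
    """
    rng = np.random.default_rng(seed)
    frags = draw_fragments(ref, n, length_model, rng)
    gc_counts = fragment_gc_counts(ref, frags)
    lengths = np.array([end - start for start, end, _ in frags])
    p = survival_probability(lengths, gc_counts, survival)
    keep = rng.random(len(frags)) < p
    return lengths[keep], (gc_counts[keep] / lengths[keep])


def stage_gcshift(config: PipelineConfig) -> dict:
    """GC-vs-length shift onsets under biased and unbiased survival."""
    world = build_world(config)
    out_dir = Path(config.out_dir) / "gcshift"
    out_dir.mkdir(parents=True, exist_ok=True)
    ref = world.references["Methanobrevibacter_oralis_synth"]
    model = LengthModel(location=60.0, scale=0.35, min_len=20, max_len=250)
    biased = SurvivalModel.sharp_length_cutoff(45.0, ref.genomic_gc)
    results = {}
    for label, survival in (("biased", biased), ("unbiased", SurvivalModel.none())):
        lengths, gcs = simulate_survival_fragments(
            ref,
            config.gc_experiment_reads,
            survival,
            model,
            stage_seed(config.seed, f"gcshift:{label}"),
        )
        result = gcshift.gc_shift(lengths, gcs, config.gcshift)
        write_table(
            result.table,
            out_dir / f"{label}.tsv",
            meta=config.meta(),
            index=False,
        )
        results[label] = result.onset_length
        logger.info("gcshift: %s onset=%s", label, result.onset_length)
    return {"onset_biased_bp": results["biased"], "onset_unbiased_bp": results["unbiased"]}


def stage_community(config: PipelineConfig) -> dict:
    """Taxon table, Bray-Curtis, PCoA, alpha diversity, source profiles."""
    world = build_world(config)
    out_dir = Path(config.out_dir) / "community"
    out_dir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, dict[str, int]] = {}
    for name in sample_names(config):
        if name == "BLANK":
            continue
        _, truths = _load_sample(config, name)
        row: dict[str, int] = {t: 0 for t in world.references}
        for truth in truths:
            row[truth.taxon_id] += 1
        counts[name] = row
    table = pd.DataFrame(counts).T.sort_index()
    table.index.name = "sample_id"
    write_table(table, out_dir / "taxon_table.tsv", meta=config.meta())
    bc = community.bray_curtis(table)
    write_table(bc, out_dir / "bray_curtis.tsv", meta=config.meta())
    ordination = community.pcoa(bc, n_axes=2)
    write_table(ordination.coordinates, out_dir / "pcoa.tsv", meta=config.meta())
    alpha = community.alpha_diversity(table)
    write_table(alpha.to_frame(), out_dir / "alpha.tsv", meta=config.meta())
    profiles = community.classify_sources(table, world.metadata)
    community.write_krona(profiles, out_dir / "krona")

    calc = [n for n in table.index if n.endswith("calculus")]
    within = [bc.loc[a, b] for a in calc for b in calc if a < b]
    to_pair = [bc.loc[c, c.replace("calculus", "dentin")] for c in calc]
    clustering = float(np.mean(within)) < float(np.mean(to_pair))
    dentin = [n for n in table.index if n.endswith("dentin")]
    alpha_ordering = float(alpha[dentin].mean()) > float(alpha[calc].mean())
    return {
        "calculus_bc_within_mean": float(np.mean(within)),
        "calculus_bc_to_paired_dentin_mean": float(np.mean(to_pair)),
        "calculus_clusters": clustering,
        "dentin_alpha_higher": alpha_ordering,
    }


def stage_authenticate(config: PipelineConfig) -> dict:
    """Authenticate host reads in a calculus sample and in the blank."""
    world = build_world(config)
    out_dir = Path(config.out_dir) / "auth"
    out_dir.mkdir(parents=True, exist_ok=True)
    auth_config = authfilter.AuthConfig(target_taxon=HOST_TAXON)
    results = {}
    for name in ("IND1_calculus", "BLANK"):
        reads, truths = _load_sample(config, name)
        host_ids = {t.read_id for t in truths if t.taxon_id == HOST_TAXON}
        host_reads = [r for r in reads if r.read_id in host_ids]
        alignments = perfect_alignments(host_reads, truths, world.references)
        assignments = {rid: HOST_TAXON for rid in host_ids}
        passed, report = authfilter.authenticate(alignments, assignments, auth_config)
        authfilter.write_report(report, out_dir / f"{name}.auth.tsv")
        results[name] = report
        logger.info(
            "authenticate: %s high-confidence=%d damage=%s",
            name,
            report.n_high_confidence,
            report.damage_status,
        )
    return {
        "calculus_damage_status": results["IND1_calculus"].damage_status,
        "blank_damage_status": results["BLANK"].damage_status,
        "blank_fails_authentication": results["BLANK"].damage_status != "positive",
    }


STAGES: dict[str, Callable[[PipelineConfig], dict]] = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "fraglen": stage_fraglen,
    "damage": stage_damage,
    "gcshift": stage_gcshift,
    "community": stage_community,
    "authenticate": stage_authenticate,
}


def run_stage(stage: str, config: PipelineConfig) -> dict:
    """Run one named stage; unknown names raise listing the valid stages."""
    if stage not in STAGES:
        raise ValueError(
            f"unknown stage {stage!r}; valid stages: {', '.join(STAGES)}"
        )
    logger.info("running stage %s (seed %d)", stage, config.seed)
    try:
        return STAGES[stage](config)
    except Exception as exc:
        raise RuntimeError(
            f"stage {stage!r} failed with seed {config.seed}: {exc}"
        ) from exc


def run_demo(seed: int = 1, out_dir: str | Path = "paleoprof_demo",
             config: PipelineConfig | None = None) -> dict:
    """Simulate the paired-sample world and run every stage.

    Returns the report dict (also written as JSON and a text summary to
    ``out_dir``) with the four qualitative assertions under 'assertions'.
    """
    if config is None:
        config = PipelineConfig(seed=seed, out_dir=str(out_dir))
    Path(config.out_dir).mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "config": config.config_hash(), "stages": {}}
    for stage in STAGES:
        report["stages"][stage] = run_stage(stage, config)
    stages = report["stages"]
    report["assertions"] = {
        "host_shorter_in_calculus": stages["fraglen"]["host_shorter_in_all_calculus"],
        "calculus_pcoa_clustering": stages["community"]["calculus_clusters"],
        "gc_onset_only_under_biased_survival": (
            stages["gcshift"]["onset_biased_bp"] is not None
            and stages["gcshift"]["onset_unbiased_bp"] is None
        ),
        "contaminants_fail_authentication": stages["authenticate"][
            "blank_fails_authentication"
        ],
    }
    report["all_assertions_pass"] = all(report["assertions"].values())
    report_path = Path(config.out_dir) / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    summary = Path(config.out_dir) / "summary.txt"
    lines = [
        f"# seed={config.seed} config={config.config_hash()}",
        f"host shorter in all calculus-like samples: "
        f"{report['assertions']['host_shorter_in_calculus']}",
        f"mean calculus host displacement (bp): "
        f"{stages['fraglen']['mean_calculus_displacement_bp']:.2f}",
        f"calculus-like samples cluster (Bray-Curtis): "
        f"{report['assertions']['calculus_pcoa_clustering']}",
        f"GC-shift onset biased/unbiased: {stages['gcshift']['onset_biased_bp']} / "
        f"{stages['gcshift']['onset_unbiased_bp']}",
        f"blank (contaminant-only) damage status: "
        f"{stages['authenticate']['blank_damage_status']}",
        f"all assertions pass: {report['all_assertions_pass']}",
    ]
    summary.write_text("\n".join(lines) + "\n")
    return report
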