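"""Run configuration and end-to-end orchestration.

``run_pipeline`` drives the full stage sequence on a synthetic dataset:
simulate -> replication profile -> peak calling -> validation against the
planted origins -> k-mer/SVM sequence model -> nucleosome/NFR analysis.  All
intermediates are written to the output directory and a deterministic JSON
report summarises peak counts, auROC, and p-values.  Unknown configuration
keys are rejected; the validated config is echoed into a sidecar so a run is
reproducible from its own output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import features as ft
from . import nucleosome as nuc
from .io import __version__, write_bed, write_bedgraph
from .peaks import PeakCallParams, call_peaks
from .profile import ProfileParams, build_profile
from .synthetic import SyntheticSpec, make_genome, simulate_nucleosome_reads, simulate_replication_reads
from .validate import OriginSet, classify_distances, overlap_significance

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


def _from_dict(cls, data: dict, where: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{where}: {exc}") from exc


@dataclass
class RunConfig:
    """Per-stage parameter blocks plus seeds and the species preset."""

    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    profile: ProfileParams = field(default_factory=ProfileParams)
    peaks: PeakCallParams = field(default_factory=PeakCallParams)
    svm_folds: int = 5
    svm_seed: int = 0
    nfr_threshold: float = 0.5
    nfr_min_width: int = 125
    n_permutations: int = 999
    nfr_permutations: int = 1000
    validation_seed: int = 0
    species_preset: str | None = None

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "replicated_fraction_n" in data.get("profile", {}) and data["profile"]["replicated_fraction_n"] is None:
            raise ConfigError("profile.replicated_fraction_n: a replicated fraction n is required")
        sub = {}
        if "synthetic" in data:
            sub["synthetic"] = _from_dict(SyntheticSpec, data.pop("synthetic"), "synthetic")
        if "profile" in data:
            sub["profile"] = _from_dict(ProfileParams, data.pop("profile"), "profile")
        if "peaks" in data:
            peaks_block = data.pop("peaks")
            preset = data.get("species_preset")
            if preset:
                sub["peaks"] = PeakCallParams.for_species(preset, **peaks_block)
            else:
                sub["peaks"] = _from_dict(PeakCallParams, peaks_block, "peaks")
        cfg = _from_dict(cls, {**data, **sub}, "config")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute every stage in order; return (and write) the run report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "config": config.to_dict()}
    stage = "simulate"
    try:
        spec = config.synthetic
        genome, truth = make_genome(spec)
        s_reads, g2_reads = simulate_replication_reads(genome, truth, spec)
        nuc_reads = simulate_nucleosome_reads(genome, truth, spec)
        lengths = spec.chrom_lengths_dict()

        stage = "profile"
        pparams = dataclasses.replace(
            config.profile, replicated_fraction_n=truth.replicated_fraction_n
        )
        prof = build_profile(s_reads, g2_reads, lengths, pparams)
        write_bedgraph(outdir / "R.bedgraph", prof.R, seed=spec.seed, config=report["config"])
        (outdir / "R.params.json").write_text(json.dumps(prof.provenance, indent=1, sort_keys=True))

        stage = "callpeaks"
        peaks, residual, template = call_peaks(prof.R, config.peaks)
        import pandas as pd

        peak_df = pd.DataFrame(
            [
                (p.chrom, int(p.position), int(p.position) + 1, str(p.serial),
                 str(int(round(1000 * (p.height - 1)))), ".")
                for p in peaks
            ],
            columns=["chrom", "start", "end", "name", "score", "strand"],
        )
        write_bed(outdir / "peaks.bed", peak_df, seed=spec.seed, config=report["config"])
        report["n_peaks"] = len(peaks)
        report["template_sigma_bp"] = round(template.sigma, 2)

        stage = "validate"
        test_set = OriginSet("called", [(p.chrom, p.position) for p in peaks])
        truth_set = OriginSet("planted", list(truth.origin_positions))
        res = overlap_significance(
            test_set, truth_set, max_dist=1000, chrom_lengths=lengths,
            n_perm=config.n_permutations, seed=config.validation_seed,
        )
        report["validation"] = {
            "counts": classify_distances(test_set, truth_set).counts,
            "p_value": res.p_value,
            "n_permutations": res.n_permutations,
        }

        stage = "features"
        loci = ft.extract_loci(
            [(p.chrom, p.position) for p in peaks], genome, truth.gene_intervals,
            seed=config.svm_seed,
        )
        matrix = ft.build_feature_matrix(loci)
        cv = ft.train_svm_cv(matrix, folds=config.svm_folds, seed=config.svm_seed)
        report["svm"] = {
            "cv_auroc": round(cv.auroc, 4),
            "n_positive": int(loci.labels.sum()),
            "n_background": int((loci.labels == 0).sum()),
        }

        stage = "nucleosome"
        occ = nuc.occupancy_from_reads(nuc_reads, lengths)
        nfrs = nuc.detect_nfrs(occ, threshold=config.nfr_threshold, min_width=config.nfr_min_width)
        depl = nuc.nfr_depletion_test(
            [(p.chrom, p.position) for p in peaks], occ, nfrs,
            n_iter=config.nfr_permutations, seed=config.validation_seed,
        )
        report["nucleosome"] = {
            "n_nfrs": len(nfrs),
            "depletion_p": depl.p_value,
            "observed_depletion": round(depl.observed_depletion, 4),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report_json = json.dumps(report, indent=1, sort_keys=True)
    (outdir / "report.json").write_text(report_json)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(report["config"], fh, sort_keys=True)
    return report
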