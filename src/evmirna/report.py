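"""End-to-end pipeline orchestration and machine-readable report assembly."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from . import __version__
from .detection import DETECTION_RULES, detect_partition, rank_abundance
from .diffexp import estimate_dispersions, fit_pairwise, summarize_pairs
from .errors import ConfigurationError
from .harmonize import harmonize_counts
from .io import CountMatrix, read_counts, read_metadata, read_raw_counts
from .normalize import cpm, pca, size_factors
from .signature import Thresholds, classify_key, tau_table, write_consensus_sets

log = logging.getLogger("evmirna")

ALL_STAGES = ("harmonize", "normalize", "detection", "diffexp", "signature")


@dataclass
class PipelineConfig:
    """Paths, thresholds and stage toggles for one pipeline run."""

    counts: str | None = None
    primary_counts: str | None = None  # dialect pair, used when counts is None
    reference_counts: str | None = None
    metadata: str | None = None
    annotations: str | None = None
    outdir: str = "evmirna_out"
    detection_rule: str = "any_replicate_nonzero"
    min_total: int = 1
    k: int = 20
    alpha: float = 0.05
    tau_thresh: float = 0.7
    fc_thresh: float = 5.0
    m: int = 2
    require_significant_fc: bool = True
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self) -> None:
        if self.detection_rule not in DETECTION_RULES:
            raise ConfigurationError(f"unknown detection rule {self.detection_rule!r}")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
        if "signature" in self.stages and "diffexp" not in self.stages:
            raise ConfigurationError("signature stage requires the diffexp stage")
        if self.counts is None and not (self.primary_counts and self.reference_counts):
            raise ConfigurationError("provide either counts or a primary/reference dialect pair")
        if self.metadata is None:
            raise ConfigurationError("metadata path is required")
        for label, path in (
            ("counts", self.counts),
            ("primary_counts", self.primary_counts),
            ("reference_counts", self.reference_counts),
            ("metadata", self.metadata),
            ("annotations", self.annotations),
        ):
            if path is not None and not Path(path).exists():
                raise ConfigurationError(f"{label} file not found: {path}")
        # threshold validation is delegated to Thresholds
        self.thresholds()

    def thresholds(self) -> Thresholds:
        return Thresholds(
            k=self.k,
            alpha=self.alpha,
            tau_thresh=self.tau_thresh,
            fc_thresh=self.fc_thresh,
            m=self.m,
            require_significant_fc=self.require_significant_fc,
        )

    def to_yaml(self) -> str:
        data = asdict(self)
        data["stages"] = list(data["stages"])
        return yaml.safe_dump(data, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigurationError(f"bad config: {exc}") from exc

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


@dataclass
class LandscapeReport:
    """Aggregated pipeline outputs; every number re-derivable from stage TSVs."""

    provenance: dict
    detection: dict | None = None
    abundance: dict | None = None
    pca: dict | None = None
    diffexp: dict | None = None
    tau: dict | None = None
    signature: dict | None = None
    harmonization: dict | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=float))


def _load_matrix(config: PipelineConfig) -> tuple[CountMatrix, dict | None]:
    groups = read_metadata(config.metadata)
    if config.counts:
        return read_counts(config.counts, config.metadata), None
    primary = read_raw_counts(config.primary_counts, config.annotations)
    reference = read_raw_counts(config.reference_counts, config.annotations)
    matrix, hlog = harmonize_counts(primary, reference, groups)
    return matrix, hlog.to_dict()


def run_pipeline(config: PipelineConfig) -> LandscapeReport:
    """Run the enabled stages in dependency order and write all artifacts.

    Identical config and seed produce an identical report body (the
    provenance block carries the config hash, not a timestamp).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    report = LandscapeReport(
        provenance={
            "package": "evmirna",
            "version": __version__,
            "config_sha256": config.digest(),
            "seed": config.seed,
        }
    )

    try:
        matrix, hlog_dict = _load_matrix(config)
        if hlog_dict is not None:
            report.harmonization = {
                "renamed": len(hlog_dict["renamed"]),
                "unresolved": len(hlog_dict["unresolved"]),
                "zero_filled_primary": len(hlog_dict["zero_filled_primary"]),
                "zero_filled_reference": len(hlog_dict["zero_filled_reference"]),
            }
            (outdir / "harmonization_log.json").write_text(json.dumps(hlog_dict, indent=2))
            matrix.write(outdir / "harmonized_counts.tsv")
        log.info("loaded %d features x %d samples", len(matrix.features), len(matrix.samples))

        cpm_mat = norm = None
        if "normalize" in config.stages:
            t = time.time()
            cpm_mat = cpm(matrix)
            cpm_mat.to_csv(outdir / "cpm.tsv", sep="\t")
            norm = size_factors(matrix)
            norm.size_factors.to_frame().to_csv(outdir / "size_factors.tsv", sep="\t")
            norm.normalized.to_csv(outdir / "normalized_counts.tsv", sep="\t")
            pres = pca(norm.log2)
            pres.scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
            report.pca = {
                "variance_fraction": [float(v) for v in pres.variance_fraction],
            }
            (outdir / "pca.json").write_text(json.dumps(pres.to_dict(), indent=2))
            log.info("normalize stage done in %.2fs", time.time() - t)

        if "detection" in config.stages:
            t = time.time()
            part = detect_partition(matrix, config.detection_rule, config.min_total)
            part.write(outdir / "detection_partition.json")
            report.detection = {
                "rule": part.rule,
                "union_size": part.union_size,
                "group_totals": {g: part.group_total(g) for g in part.group_names},
                "exclusive": {g: len(part.exclusive(g)) for g in part.group_names},
                "all_groups_cell": len(part.cell(*part.group_names)),
            }
            if cpm_mat is not None:
                ranking = rank_abundance(cpm_mat, matrix.groups, config.k)
                for g, table in ranking.tables.items():
                    table.assign(
                        common_abundant=table["feature"].isin(ranking.common_abundant),
                        uniquely_abundant=table["feature"].isin(ranking.uniquely_abundant[g]),
                    ).to_csv(outdir / f"top{config.k}_{g}.tsv", sep="\t", index=False)
                report.abundance = {
                    "k": config.k,
                    "common_abundant": sorted(ranking.common_abundant),
                    "uniquely_abundant": {
                        g: sorted(v) for g, v in ranking.uniquely_abundant.items()
                    },
                }
            log.info("detection stage done in %.2fs", time.time() - t)

        tables = None
        if "diffexp" in config.stages:
            t = time.time()
            if norm is None:
                norm = size_factors(matrix)
            disp = estimate_dispersions(matrix, norm)
            tables = fit_pairwise(matrix, norm, disp)
            for (a, b), table in tables.items():
                table.to_csv(outdir / f"de_{a}_vs_{b}.tsv", sep="\t", index=False)
            report.diffexp = summarize_pairs(tables, config.alpha)
            log.info("diffexp stage done in %.2fs", time.time() - t)

        if "signature" in config.stages:
            t = time.time()
            assert tables is not None and norm is not None
            taus = tau_table(norm.group_means(matrix))
            taus.to_csv(outdir / "tau.tsv", sep="\t")
            if cpm_mat is None:
                cpm_mat = cpm(matrix)
            ranking = rank_abundance(cpm_mat, matrix.groups, config.k)
            keys = classify_key(
                ranking, tables, taus, matrix.group_names, config.thresholds()
            )
            keys.to_csv(outdir / "key_signature.tsv", sep="\t", index=False)
            consensus = write_consensus_sets(
                tables, matrix.group_names, outdir / "consensus_upregulated.json", config.alpha
            )
            finite_tau = taus["tau"].dropna()
            report.tau = {
                "n_defined": int(finite_tau.size),
                "mean": float(finite_tau.mean()) if finite_tau.size else None,
                "n_above_thresh": int((finite_tau > config.tau_thresh).sum()),
            }
            report.signature = {
                "key_calls": {
                    g: sorted(keys.loc[(keys["subtype"] == g) & keys["key"], "feature"])
                    for g in matrix.group_names
                },
                "consensus_upregulated": {g: v for g, v in consensus.items()},
            }
            log.info("signature stage done in %.2fs", time.time() - t)

        report.write(outdir / "report.json")
        log.info("pipeline finished in %.2fs", time.time() - t0)
        return report
    except Exception:
        (outdir / "FAILED").write_text("pipeline failed; partial outputs retained\n")
        raise
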