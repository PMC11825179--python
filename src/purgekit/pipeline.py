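"""End-to-end orchestration: filters -> ROH -> diversity -> load -> purging
statistics -> SFS, with per-stage TSV outputs and one JSON report.

The run is configured by a YAML mapping (see :class:`RunConfig`); a single
seed governs every stochastic step, with per-stage seeds derived from it
deterministically.  Every parameter value after default-filling is logged so
a run is reconstructible from the log alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import variants_io as vio
from .diversity import individual_heterozygosity, windowed_pi
from .load_annotation import (
    CATEGORIES,
    classify_effects,
    hom_load_ratio,
    polarize,
    tabulate_load,
)
from .purging_stats import (
    ConservationTrack,
    gerp_relative_load,
    rohf_statistics,
    rxy,
    sfs,
)
from .roh import (
    ROHParams,
    compute_froh,
    detect_roh,
    filter_roh_min_length,
    segments_to_frame,
    summarize_inbreeding,
)
from .synthetic_data import PopulationConfig, SimConfig, simulate

logger = logging.getLogger("purgekit")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Parsed run configuration.

    Exactly one of ``inputs`` (paths to VCF + sidecar tables) or
    ``simulate`` (a SimConfig mapping) must be provided.  Stage blocks
    (``roh``, ``diversity``, ``load``, ``purging``, ``sfs``) are opt-in:
    an absent block skips that stage and its report section.
    """

    output_dir: str = "purgekit_out"
    seed: int = 0
    inputs: dict | None = None
    simulate: dict | None = None
    focal_population: str | None = None
    roh: dict | None = field(default_factory=dict)
    diversity: dict | None = field(default_factory=dict)
    load: dict | None = field(default_factory=dict)
    purging: dict | None = field(default_factory=dict)
    sfs: dict | None = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if (cfg.inputs is None) == (cfg.simulate is None):
            raise ValueError("config needs exactly one of 'inputs' or 'simulate'")
        return cfg


def _sim_config_from_block(block: dict, seed: int) -> SimConfig:
    block = dict(block)
    pops = block.pop("populations", None)
    cfg = SimConfig(seed=seed, **block)
    if pops is not None:
        cfg.populations = {
            name: PopulationConfig(**(p or {})) for name, p in pops.items()
        }
    return cfg


def _load_inputs(cfg: RunConfig):
    paths = cfg.inputs
    vt = vio.read_vcf(paths["vcf"])
    panel = vio.read_panel(paths["panel"])
    layout = vio.read_layout(paths["layout"], paths.get("autosomes"))
    effects_raw = pd.read_csv(
        paths["effects"], sep="\t", header=None,
        names=["chrom", "pos", "term", "aa_ref", "aa_alt"],
        dtype={"chrom": str, "pos": np.int64},
    )
    outgroup = vio.read_site_table(paths["outgroup"], "base") if "outgroup" in paths else None
    track = None
    if "scores" in paths:
        sc = pd.read_csv(paths["scores"], sep="\t", header=None,
                         names=["chrom", "pos", "score"],
                         dtype={"chrom": str, "pos": np.int64, "score": float})
        track = sc
    return vt, panel, layout, effects_raw, outgroup, track


def _align_site_table(vt, table: pd.DataFrame, columns) -> pd.DataFrame:
    """Left-join a per-site table onto the variant table's (chrom, pos) keys."""
    key = vt.sites[["chrom", "pos"]].copy()
    key["chrom"] = key["chrom"].astype(str)
    table = table.copy()
    table["chrom"] = table["chrom"].astype(str)
    merged = key.merge(table, on=["chrom", "pos"], how="left")
    return merged[["chrom", "pos", *columns]]


def run_all(cfg: RunConfig) -> dict:
    """Execute all configured stages; returns the report dict.

    Writes per-stage TSVs, ``report.json`` and ``run.log`` under
    ``cfg.output_dir``.  On a stage failure, partial outputs are kept, a
    ``FAILED`` marker naming the stage is written, and :class:`StageError`
    is raised.
    """
    outdir = cfg.output_dir
    os.makedirs(outdir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(outdir, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(cfg.log_level)
    report: dict = {"seed": cfg.seed, "parameters": {}}
    stage = "setup"
    try:
        from . import __version__

        logger.info("purgekit %s seed=%d", __version__, cfg.seed)
        report["version"] = __version__

        # ---- inputs
        stage = "inputs"
        if cfg.simulate is not None:
            sim_cfg = _sim_config_from_block(cfg.simulate, cfg.seed)
            logger.info("simulate: %s", sim_cfg)
            sim = simulate(sim_cfg)
            vt, panel, layout = sim.variants, sim.panel, sim.layout
            effects = sim.effects
            outgroup = sim.outgroup
            scores_df = pd.DataFrame(
                {"chrom": vt.sites["chrom"], "pos": vt.sites["pos"],
                 "score": sim.track.scores}
            )
        else:
            vt, panel, layout, effects_raw, outgroup, scores_df = _load_inputs(cfg)
            effects = None
            if effects_raw is not None:
                effects = classify_effects(effects_raw.fillna({"term": ""}))

        # ---- site filters
        stage = "filters"
        n0 = vt.n_sites
        vt = vio.filter_biallelic_snps(vt)
        vt = vio.apply_hard_filter(vt)
        vt = vio.filter_missingness(vt, panel)
        logger.info("filters: %d -> %d sites", n0, vt.n_sites)
        report["filters"] = {"sites_in": n0, "sites_out": vt.n_sites}
        if effects is not None:
            effects = _align_site_table(
                vt, effects, ["effect", "aa_ref", "aa_alt", "dnssnp", "term"]
            )
            effects["effect"] = effects["effect"].fillna("other")
            effects["dnssnp"] = effects["dnssnp"].fillna(False).astype(bool)

        # ---- ROH
        segs_by_sample = {}
        if cfg.roh is not None:
            stage = "roh"
            params = ROHParams(**{k: v for k, v in (cfg.roh or {}).items()})
            report["parameters"]["roh"] = dataclasses.asdict(params)
            logger.info("roh params: %s", params)
            auto_mask = vt.sites["chrom"].astype(str).isin(layout.autosomes).to_numpy()
            vt_auto = vt.take_sites(auto_mask)
            for sample in vt.samples:
                segs = detect_roh(vt_auto, sample, params)
                segs_by_sample[sample] = filter_roh_min_length(
                    segs, int(params.final_min_length_kb * 1000)
                )
            summary = summarize_inbreeding(segs_by_sample, layout, panel)
            all_segs = [s for segs in segs_by_sample.values() for s in segs]
            segments_to_frame(all_segs).to_csv(
                os.path.join(outdir, "roh_segments.tsv"), sep="\t", index=False
            )
            summary.per_sample.to_csv(
                os.path.join(outdir, "roh_per_sample.tsv"), sep="\t", index=False
            )
            report["roh"] = {
                "per_population": summary.per_population.to_dict("records"),
                "fraction_below_1mb": summary.fraction_below_1mb,
                "froh_per_sample": dict(
                    zip(summary.per_sample["sample"], summary.per_sample["froh"])
                ),
                "froh_ge_1mb_per_sample": dict(
                    zip(summary.per_sample["sample"], summary.per_sample["froh_ge_1mb"])
                ),
            }

        # ---- diversity
        if cfg.diversity is not None:
            stage = "diversity"
            window_bp = int((cfg.diversity or {}).get("window_bp", 500_000))
            report["parameters"]["diversity"] = {"window_bp": window_bp}
            div = windowed_pi(vt, panel, window_bp, chrom_lengths=layout.lengths)
            het = individual_heterozygosity(vt)
            div.windows.to_csv(
                os.path.join(outdir, "windowed_pi.tsv"), sep="\t", index=False
            )
            het.to_csv(os.path.join(outdir, "heterozygosity.tsv"), sep="\t", index=False)
            report["diversity"] = {
                "pi": div.genome_pi,
                "het_per_sample": dict(zip(het["sample"], het["het_rate"])),
            }

        # ---- polarization + load
        polar = None
        if cfg.load is not None and effects is not None and outgroup is not None:
            stage = "load"
            focal = cfg.focal_population or next(iter(panel.populations))
            report["parameters"]["load"] = {"focal_population": focal}
            outg = _align_site_table(vt, outgroup, ["base"]).dropna(subset=["base"])
            polar = polarize(vt, outg, panel, focal)
            counts = tabulate_load(vt, effects, polar, panel)
            counts.per_individual.to_csv(
                os.path.join(outdir, "load_per_individual.tsv"), sep="\t", index=False
            )
            hom_ratios = {
                cat: hom_load_ratio(counts, cat)
                .groupby("population")["hom_ratio"].mean().to_dict()
                for cat in CATEGORIES
            }
            report["load"] = {
                "n_polarized": int(polar.resolved.sum()),
                "per_population": counts.per_population.to_dict("records"),
                "hom_ratio": hom_ratios,
            }

        # ---- purging statistics
        if cfg.purging is not None and polar is not None:
            stage = "purging"
            block = cfg.purging or {}
            report["parameters"]["purging"] = dict(block)
            rohf = rohf_statistics(vt, effects, polar, panel, segs_by_sample)
            rohf.per_individual.to_csv(
                os.path.join(outdir, "rohf_per_individual.tsv"), sep="\t", index=False
            )
            rohf.per_population.to_csv(
                os.path.join(outdir, "rohf_per_population.tsv"), sep="\t", index=False
            )
            report["purging"] = {
                "rohf": rohf.per_population.to_dict("records"),
                "rxy": [],
            }
            from .load_annotation import category_masks

            masks = category_masks(effects)
            intergenic = (effects["effect"] == "intergenic").to_numpy()
            pops = list(panel.populations)
            pairs = block.get(
                "rxy_pairs",
                [[x, y] for i, x in enumerate(pops) for y in pops[i + 1:]],
            )
            n_blocks = int(block.get("n_blocks", 20))
            for x, y in pairs:
                for cat in ("LoF", "missense", "dnsSNP", "synonymous"):
                    if not masks[cat].any():
                        continue
                    res = rxy(polar, x, y, masks[cat], intergenic, n_blocks)
                    report["purging"]["rxy"].append(
                        {"x": x, "y": y, "category": cat,
                         "r": res.r, "se": res.se, "n_blocks": res.n_blocks}
                    )
            if scores_df is not None:
                aligned = _align_site_table(vt, scores_df, ["score"])
                scores = aligned["score"].to_numpy(dtype=float)
                scores = np.where(np.isnan(scores), -np.inf, scores)
                track = ConservationTrack(scores, float(block.get("quantile", 0.001)))
                gerp = gerp_relative_load(vt, polar, track, panel)
                gerp.per_individual.to_csv(
                    os.path.join(outdir, "gerp_load.tsv"), sep="\t", index=False
                )
                report["purging"]["gerp"] = {
                    "threshold": track.threshold,
                    "per_population": gerp.per_individual.groupby("population")
                    ["relative_load"].mean().to_dict(),
                }

        # ---- SFS
        if cfg.sfs is not None and polar is not None:
            stage = "sfs"
            block = cfg.sfs or {}
            mode = block.get("mode", "expected")
            report["parameters"]["sfs"] = dict(block)
            report["sfs"] = {}
            for pop, members in panel.populations.items():
                sub2n = int(block.get("subsample_2n", 2 * len(members)))
                res = sfs(polar, effects, panel, pop, sub2n, mode=mode,
                          seed=_derive_seed(cfg.seed, pop))
                report["sfs"][pop] = {
                    "subsample_2n": sub2n,
                    "spectra": {c: list(map(float, v)) for c, v in res.spectra.items()},
                    "proportion_fixed": res.proportion_fixed(),
                }

        stage = "report"
        report_path = os.path.join(outdir, "report.json")
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=2, default=_json_default)
        validate_report(report)
        logger.info("report written to %s", report_path)
        return report
    except Exception as exc:
        with open(os.path.join(outdir, "FAILED"), "w") as fh:
            fh.write(f"stage: {stage}\ncause: {exc}\n")
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc
    finally:
        logger.removeHandler(handler)
        handler.close()


def _derive_seed(seed: int, label: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    import zlib

    return (seed * 1_000_003 + zlib.crc32(label.encode())) % (2**31 - 1)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# Report schema validation (minimal structural check against the shipped schema)
# ---------------------------------------------------------------------------

def _schema_path() -> str:
    return os.path.join(os.path.dirname(__file__), "report_schema.json")


def validate_report(report: dict) -> None:
    """Check the report against the shipped JSON schema (types + required)."""
    with open(_schema_path()) as fh:
        schema = json.load(fh)
    _check(report, schema, "$")


_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "number": (int, float),
    "integer": int,
    "boolean": bool,
}


def _check(value, schema: dict, path: str) -> None:
    t = schema.get("type")
    if t is not None:
        expected = _TYPES[t]
        if t == "number" and value is None:
            pass  # NaN serialized as null is tolerated
        elif not isinstance(value, expected) or (
            t in ("number", "integer") and isinstance(value, bool)
        ):
            raise ValueError(f"report{path}: expected {t}, got {type(value).__name__}")
    for key in schema.get("required", []):
        if key not in value:
            raise ValueError(f"report{path}: missing required key {key!r}")
    for key, sub in schema.get("properties", {}).items():
        if isinstance(value, dict) and key in value:
            _check(value[key], sub, f"{path}.{key}")
    if "items" in schema and isinstance(value, list):
        for i, item in enumerate(value):
            _check(item, schema["items"], f"{path}[{i}]")
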