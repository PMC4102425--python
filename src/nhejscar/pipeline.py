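"""End-to-end orchestration: construct -> calls -> null -> cohort reports.

A :class:`RunConfig` names the inputs; :func:`run_pipeline` validates them
before any computation, runs every stage, and writes plain-text outputs plus
a machine-readable manifest (seed, parameter echo, stage counts).  Runs with
identical config and seed produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

from . import __version__
from .caller import CallParams, batch_analyze
from .construct import derive_cut_reference, detection_window, load_construct
from .io import read_junction_fasta, write_tsv
from .null import mh_excess_test, random_joining_distribution
from .stats import compare_cohorts, nhej_efficiency, read_facs_table, summarize

log = logging.getLogger("nhejscar")


class ConfigError(ValueError):
    """A run configuration references missing inputs or is malformed."""


@dataclass
class RunConfig:
    construct_fasta: Path
    construct_annotation: Path
    reads: dict[str, Path]                       # cohort label -> FASTA
    out_dir: Path
    facs: Optional[Path] = None
    comparisons: Sequence[tuple[str, str]] = ()  # (young label, old label)
    seed: int = 0
    dedupe: bool = True
    mmej_min: int = 5
    mmej_max: int = 25
    max_mismatch: int = 0
    kmin: int = 1
    null_mode: str = "junction"
    full_intron_null: bool = False
    large_del_threshold: int = 500
    detect_ad_retention: bool = False

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent
        try:
            reads = {str(k): base / v for k, v in raw["reads"].items()}
            cfg = cls(
                construct_fasta=base / raw["construct_fasta"],
                construct_annotation=base / raw["construct_annotation"],
                reads=reads,
                out_dir=base / raw["out_dir"],
            )
        except KeyError as exc:
            raise ConfigError(f"run config missing required key: {exc}") from exc
        if raw.get("facs"):
            cfg.facs = base / raw["facs"]
        cfg.comparisons = [tuple(pair) for pair in raw.get("comparisons", [])]
        for key in ("seed", "dedupe", "mmej_min", "mmej_max", "max_mismatch",
                    "kmin", "null_mode", "full_intron_null", "large_del_threshold",
                    "detect_ad_retention"):
            if key in raw:
                setattr(cfg, key, raw[key])
        return cfg

    def validate(self) -> None:
        missing = [
            str(p)
            for p in [self.construct_fasta, self.construct_annotation,
                      *self.reads.values(), *( [self.facs] if self.facs else [] )]
            if not Path(p).exists()
        ]
        if missing:
            raise ConfigError(f"missing input files: {missing}")
        if not self.reads:
            raise ConfigError("run config names no reads paths")
        for a, b in self.comparisons:
            for label in (a, b):
                if label not in self.reads:
                    raise ConfigError(f"comparison references unknown cohort {label!r}")


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and write the output tree; returns the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "nhejscar",
        "version": __version__,
        "seed": config.seed,
        "config": {k: (str(v) if isinstance(v, Path) else v)
                   for k, v in asdict(config).items()
                   if k != "reads"},
        "reads": {k: str(v) for k, v in config.reads.items()},
        "stages": {},
    }
    params = CallParams(
        mmej_min=config.mmej_min,
        mmej_max=config.mmej_max,
        max_mismatch=config.max_mismatch,
        detect_ad_retention=config.detect_ad_retention,
    )

    def stage(name):
        t0 = time.perf_counter()

        def done(**counts):
            manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3), **counts}
            log.info("stage %s done in %.2fs %s", name, time.perf_counter() - t0, counts)

        return done

    try:
        done = stage("construct")
        construct = load_construct(config.construct_fasta, config.construct_annotation)
        cutref = derive_cut_reference(construct)
        window = detection_window(construct, cutref)
        params = CallParams(**{**asdict(params), "window": window})
        done(max_del_5prime=window.max_del_5prime, max_del_3prime=window.max_del_3prime)
    except Exception as exc:
        raise RuntimeError(f"stage 'construct' failed: {exc}") from exc

    all_events, all_rejects = [], []
    for label, path in config.reads.items():
        try:
            done = stage(f"analyze:{label}")
            reads = read_junction_fasta(path)
            events, rejects, info = batch_analyze(
                reads, cutref, params, construct=construct, dedupe=config.dedupe
            )
            events.insert(0, "cohort_label", label)
            rejects.insert(0, "cohort_label", label)
            all_events.append(events)
            all_rejects.append(rejects)
            done(**info)
        except Exception as exc:
            raise RuntimeError(f"stage 'analyze' failed on cohort {label!r}: {exc}") from exc
    events = pd.concat(all_events, ignore_index=True)
    rejects = pd.concat(all_rejects, ignore_index=True)
    write_tsv(events, out / "events.tsv")
    write_tsv(rejects, out / "rejects.tsv")

    try:
        done = stage("null")
        null = random_joining_distribution(
            cutref,
            None if config.full_intron_null else window,
            mode=config.null_mode,
        )
        write_tsv(null.to_frame(), out / "null_distribution.tsv")
        (out / "null_summary.json").write_text(
            json.dumps(
                {"n_pairs": null.n_pairs, "max_mh": null.max_mh,
                 "p_mh_ge_1": null.p_mh_ge.get(1, 0.0), "mode": config.null_mode},
                indent=2,
            )
            + "\n"
        )
        done(n_pairs=null.n_pairs, max_mh=null.max_mh)
    except Exception as exc:
        raise RuntimeError(f"stage 'null' failed: {exc}") from exc

    try:
        done = stage("summarize")
        summaries, excess_rows = [], []
        for label in config.reads:
            ev = events[events["cohort_label"] == label]
            s = summarize(ev, params, cohort=label,
                          large_del_threshold=config.large_del_threshold)
            summaries.append(asdict(s))
            # like-for-like: the null enumerates insertion-free junctions,
            # and an inserted junction cannot display microhomology
            ins_free = ev[ev["insertion_len"] == 0]
            res = mh_excess_test(ins_free, null, k_min=config.kmin)
            excess_rows.append(
                {"cohort": label, "observed_frac": res.estimate1,
                 "expected_frac": res.estimate2, "statistic": res.statistic,
                 "p_value": res.p_value, "degenerate": res.degenerate,
                 "n_insertion_free": len(ins_free)}
            )
        write_tsv(pd.DataFrame(summaries), out / "summary.tsv")
        write_tsv(pd.DataFrame(excess_rows), out / "mh_excess.tsv")
        done(n_cohorts=len(summaries))
    except Exception as exc:
        raise RuntimeError(f"stage 'summarize' failed: {exc}") from exc

    if config.comparisons:
        try:
            done = stage("compare")
            tables = []
            for young_label, old_label in config.comparisons:
                tab = compare_cohorts(
                    events[events["cohort_label"] == young_label],
                    events[events["cohort_label"] == old_label],
                    params,
                    labels=("young", "old"),
                    large_del_threshold=config.large_del_threshold,
                )
                tab.insert(0, "pair", f"{young_label}_vs_{old_label}")
                tables.append(tab)
            write_tsv(pd.concat(tables, ignore_index=True), out / "comparisons.tsv")
            done(n_pairs=len(tables))
        except Exception as exc:
            raise RuntimeError(f"stage 'compare' failed: {exc}") from exc

    if config.facs:
        try:
            done = stage("efficiency")
            counts = read_facs_table(config.facs)
            eff = pd.DataFrame(
                {
                    "sample": [c.sample for c in counts],
                    "n_gfp": [c.n_gfp for c in counts],
                    "n_dsred": [c.n_dsred for c in counts],
                    "efficiency": [nhej_efficiency(c) for c in counts],
                }
            )
            write_tsv(eff, out / "efficiency.tsv")
            done(n_samples=len(eff))
        except Exception as exc:
            raise RuntimeError(f"stage 'efficiency' failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
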