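"""End-to-end orchestration: simulate/read -> segment -> profile -> tables ->
extend -> resolve -> consensus, with a reproducible manifest.

Every output file is hashed into ``manifest.json``; identical config + seed
produce identical hashes. The single global seed fans out to per-stage seeds
keyed by stage name, so stage-level reproducibility is independent of
execution order.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import autocorr, extension, isochores, ngram, patterns, seqio, synth

__all__ = ["RunConfig", "run_all", "stage_seed"]

log = logging.getLogger("isopattern")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed (stage-name keyed, < 2**31)."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """One document describing a full run; exactly one of fasta/synthetic."""

    outdir: str
    fasta: str | None = None
    synthetic: dict | None = None
    scheme: str = "five"  # "five" | "six"
    window: int = isochores.DEFAULT_WINDOW
    dinucleotides: list[str] = field(default_factory=lambda: ["CG"])
    d_min: int = 2
    d_max: int = 80
    smooth_window: int = 3
    extension_contains: list[str] = field(default_factory=list)  # e.g. ["CG"]
    max_run: int = 5
    max_steps: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.fasta is None) == (self.synthetic is None):
            raise ValueError("config needs exactly one of 'fasta' or 'synthetic'")
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")
        if self.fasta is not None and not Path(self.fasta).exists():
            raise FileNotFoundError(f"input FASTA not found: {self.fasta}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def isochore_scheme(self) -> isochores.IsochoreScheme:
        if self.scheme == "five":
            return isochores.FIVE_CLASS
        if self.scheme == "six":
            return isochores.SIX_CLASS
        raise ValueError(f"unknown scheme {self.scheme!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}

    def record(stage: str, *paths: Path) -> None:
        for p in paths:
            manifest["files"][p.name] = _sha256(p)
        manifest["stages"].setdefault(stage, []).extend(p.name for p in paths)

    def timed(stage: str):
        t0 = time.perf_counter()
        log.info("stage %s: start", stage)
        return lambda: log.info("stage %s: done in %.2fs", stage, time.perf_counter() - t0)

    # -- input -----------------------------------------------------------
    if config.synthetic is not None:
        done = timed("simulate")
        spec = synth.SyntheticSpec.from_dict(
            {**config.synthetic, "seed": config.synthetic.get("seed", stage_seed(config.seed, "simulate"))}
        )
        seq, truth = synth.generate_genome(spec)
        genome = [seq]
        fa = outdir / "genome.fa"
        seqio.write_fasta(genome, fa)
        tj = outdir / "truth.json"
        truth.to_json(tj)
        tb = outdir / "truth_segments.bed"
        seqio.write_bed(
            [
                isochores.IsochoreSegment(
                    s["name"], s["start"], s["end"], s["class_label"], s["realized_gc"]
                )
                for s in truth.segments
            ],
            tb,
        )
        record("simulate", fa, tj, tb)
        done()
    else:
        genome = seqio.read_fasta(config.fasta)

    # -- segmentation ----------------------------------------------------
    done = timed("segment")
    scheme = config.isochore_scheme()
    windows, segments = isochores.segment_genome(genome, config.window, scheme)
    wpath = outdir / "windows.tsv"
    seqio.write_tsv(
        pd.DataFrame(
            [
                (w.name, w.start, w.end, round(w.gc, 6), round(w.unmasked_fraction, 6), w.label)
                for w in windows
            ],
            columns=["sequence", "start", "end", "gc", "unmasked_fraction", "class"],
        ),
        wpath,
    )
    spath = outdir / "segments.bed"
    seqio.write_bed(segments, spath)
    record("segment", wpath, spath)
    done()

    # -- autocorrelation -------------------------------------------------
    done = timed("autocorr")
    rows = []
    peaks_doc: dict = {}
    for dinuc in config.dinucleotides:
        profiles = autocorr.profile_by_isochore(
            genome, segments, dinuc, config.d_min, config.d_max, config.smooth_window
        )
        for label, prof in sorted(profiles.items()):
            for d, r, nz, sm in zip(prof.distances, prof.raw, prof.normalized, prof.smoothed):
                rows.append((dinuc, label, int(d), int(r), round(float(nz), 6), round(float(sm), 6)))
            peaks = autocorr.profile_peaks(prof)
            entry: dict = {
                "norm_constant": prof.norm_constant,
                "n_occurrences": prof.n_occurrences,
                "peaks": peaks.positions,
                "peak_heights": [round(v, 4) for v in peaks.values],
            }
            if len(peaks) >= 2:
                est = autocorr.estimate_period(peaks)
                entry["period"] = est.period
                entry["residual_rms"] = est.residual_rms
            peaks_doc.setdefault(dinuc, {})[label] = entry
    ppath = outdir / "profiles.tsv"
    seqio.write_tsv(
        pd.DataFrame(rows, columns=["dinucleotide", "class", "distance", "raw", "normalized", "smoothed"]),
        ppath,
    )
    jpath = outdir / "peaks.json"
    jpath.write_text(json.dumps(peaks_doc, indent=1, sort_keys=True))
    record("autocorr", ppath, jpath)
    done()

    # -- trinucleotide tables --------------------------------------------
    done = timed("ngram")
    tables = ngram.table_by_isochore(genome, segments)
    trows = []
    for label, table in sorted(tables.items()):
        total = table.total or 1
        for rank, t in enumerate(table.ranking, start=1):
            trows.append((label, rank, t, table[t], round(table[t] / total, 6)))
    tpath = outdir / "tables.tsv"
    seqio.write_tsv(
        pd.DataFrame(trows, columns=["class", "rank", "triplet", "count", "frequency"]), tpath
    )
    record("ngram", tpath)
    done()

    # -- extension + resolution ------------------------------------------
    done = timed("extend")
    motifs_doc: dict = {}
    resolved_doc: dict = {}
    resolved_for_consensus: list[patterns.ResolvedMotif] = []
    for label, table in sorted(tables.items()):
        if table.total == 0:
            continue
        seeds = [extension.seed_select(table)]
        for dinuc in config.extension_contains:
            s = extension.seed_select(table, must_contain=dinuc)
            if s not in seeds:
                seeds.append(s)
        for seed in seeds:
            motif = extension.extend(table, seed, max_steps=config.max_steps)
            key = f"{label}:{seed}"
            motifs_doc[key] = {
                "seed": seed,
                "notation": motif.notation,
                "trace": [
                    {k: v for k, v in vars(step).items() if v is not None}
                    for step in motif.trace
                ],
            }
            try:
                res = patterns.resolve(motif, max_run=config.max_run)
            except ValueError as exc:
                resolved_doc[key] = {"error": str(exc)}
                continue
            resolved_doc[key] = {
                "sequence": res.sequence,
                "ry": patterns.ry_project(res.sequence),
                "agreement": round(res.agreement, 4),
                "chosen_counts": res.chosen_counts,
                "flank_copies": res.flank_copies,
            }
            if seed == seeds[0]:
                resolved_for_consensus.append(res)
    mpath = outdir / "motifs.json"
    mpath.write_text(json.dumps(motifs_doc, indent=1, sort_keys=True))
    rpath = outdir / "resolved.json"
    rpath.write_text(json.dumps(resolved_doc, indent=1, sort_keys=True))
    record("extend", mpath)
    record("resolve", rpath)
    done()

    # -- consensus across classes ----------------------------------------
    if len(resolved_for_consensus) >= 2:
        done = timed("consensus")
        cpath = outdir / "consensus.txt"
        try:
            cons = patterns.consensus(resolved_for_consensus)
            cpath.write_text(cons.iupac + "\n" + cons.ry() + "\n")
        except ValueError as exc:
            cpath.write_text(f"# no consensus: {exc}\n")
        record("consensus", cpath)
        done()

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
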