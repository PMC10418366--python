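"""End-to-end orchestration: load chi1 series for two conditions, compute
pairwise S_NO, select responsive residues, summarize rotamer stability, and
tabulate charge schemes — writing a reproducible report.

The run is configured by a structured dict (typically loaded from YAML or
JSON) and an input manifest listing one angle file per residue, condition
and replicate.  Every number in the report is recomputable from the
manifest plus config; a provenance block records the config hash, seed and
package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .angle_io import DihedralSeries, read_angle_table, read_chi_xvg, stack_angles
from .charges import (
    Mutation,
    apply_mutation,
    count_ionizables,
    net_charge,
    read_fasta,
    scheme_by_name,
)
from .rotamers import (
    DEFAULT_WINDOWS,
    RotamerWindows,
    classify_states,
    summarize_stability,
)
from .sno import (
    DEFAULT_BINWIDTH,
    PairSnoTable,
    SelectionConfig,
    aggregate_sno,
    pairwise_sno,
    select_responsive,
)

__all__ = ["RunConfig", "Report", "run_pipeline", "load_manifest", "charge_table"]

log = logging.getLogger("chi1sno")


class ManifestError(ValueError):
    """Missing files or inconsistent replicate structure in the manifest."""


@dataclass(frozen=True)
class RunConfig:
    """Analysis configuration mirroring the variant x pH x replicate roster."""

    manifest: str
    condition_a: str = "pH7"
    condition_b: str = "pH2"
    binwidth: float = DEFAULT_BINWIDTH
    pairing: str = "matched"
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    windows: RotamerWindows = DEFAULT_WINDOWS
    min_dwell: float = 1.0
    rotamer_residues: tuple[int, ...] = (275,)
    sequence_fasta: str | None = None
    numbering_offset: int = 115
    mutations: tuple[str, ...] = ()
    schemes: tuple[str, ...] = ("pH7", "pH2_all", "pH2_his")
    outdir: str = "chi1sno_out"
    seed: int = 0

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        d = dict(d)
        if "selection" in d and isinstance(d["selection"], Mapping):
            d["selection"] = SelectionConfig(**d["selection"])
        if "windows" in d and isinstance(d["windows"], (list, tuple)):
            d["windows"] = RotamerWindows(
                states=tuple(tuple(s) for s in d["windows"])
            )
        for key in ("mutations", "schemes", "rotamer_residues"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class Report:
    """All pipeline outputs plus a provenance block."""

    sno_table: PairSnoTable
    sno_summary: pd.DataFrame
    selected: list[int]
    stability: pd.DataFrame
    charges: pd.DataFrame | None
    provenance: dict

    def to_json_dict(self) -> dict:
        return {
            "sno": self.sno_table.to_frame().reset_index().to_dict("records"),
            "sno_summary": self.sno_summary.to_dict("records"),
            "selected_residues": self.selected,
            "stability": self.stability.to_dict("records"),
            "charges": (
                None if self.charges is None else self.charges.to_dict("records")
            ),
            "provenance": self.provenance,
        }


def load_manifest(
    manifest_path: str | Path,
) -> dict[str, dict[int, list[DihedralSeries]]]:
    """Read every angle file referenced by a JSON manifest.

    The manifest maps ``conditions -> {residue_id: [file, ...]}`` with paths
    relative to the manifest location; ``.xvg`` files are parsed in the
    chi-utility dialect, anything else as a delimited table.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    base = manifest_path.parent
    missing: list[str] = []
    data: dict[str, dict[int, list[DihedralSeries]]] = {}
    for condition, residues in manifest["conditions"].items():
        data[condition] = {}
        for rid_str, files in residues.items():
            rid = int(rid_str)
            series_list = []
            for f in files:
                path = base / f
                if not path.exists():
                    missing.append(str(path))
                    continue
                if path.suffix == ".xvg":
                    series_list.append(read_chi_xvg(path, residue_id=rid))
                else:
                    series_list.append(read_angle_table(path, residue_id=rid))
            data[condition][rid] = series_list
    if missing:
        raise ManifestError(
            "manifest references missing files: " + ", ".join(missing)
        )
    return data


def charge_table(
    fasta: str | Path,
    numbering_offset: int,
    mutations: tuple[str, ...],
    scheme_names: tuple[str, ...],
) -> pd.DataFrame:
    """Net charge per variant x scheme, reproducing the roster charge column."""
    wt = read_fasta(fasta, numbering_offset=numbering_offset)
    variants = {"WT": wt}
    for mtext in mutations:
        m = Mutation.parse(mtext)
        variants[str(m)] = apply_mutation(wt, m)
    rows = []
    for vname, seq in variants.items():
        counts = count_ionizables(seq)
        row: dict[str, Any] = {"variant": vname, **counts}
        for sname in scheme_names:
            row[sname] = net_charge(seq, scheme_by_name(sname))
        rows.append(row)
    return pd.DataFrame(rows)


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> Report:
    """Execute the full analysis and write report artifacts to cfg.outdir."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        data = load_manifest(cfg.manifest)
        for cond in (cfg.condition_a, cfg.condition_b):
            if cond not in data:
                raise ManifestError(f"condition {cond!r} absent from manifest")
        cond_a, cond_b = data[cfg.condition_a], data[cfg.condition_b]
        log.info(
            "loaded %d residues x (%s, %s)",
            len(cond_a), cfg.condition_a, cfg.condition_b,
        )

        table = pairwise_sno(
            cond_a, cond_b, pairing=cfg.pairing, binwidth=cfg.binwidth,
            labels=(cfg.condition_a, cfg.condition_b),
        )
        selected = select_responsive(table, cfg.selection)
        log.info("selected %d responsive residues: %s", len(selected), selected)

        summary_rows = []
        for i, rid in enumerate(table.residues):
            mean, sd = aggregate_sno(table.values[i])
            summary_rows.append(
                {"residue_id": rid, "mean_sno": mean, "sd_sno": sd,
                 "selected": rid in selected}
            )
        sno_summary = pd.DataFrame(summary_rows)

        traces = {}
        for rid in cfg.rotamer_residues:
            for cond_name, cond in (
                (cfg.condition_a, cond_a), (cfg.condition_b, cond_b),
            ):
                if rid not in cond:
                    continue
                for rep, series in enumerate(cond[rid], start=1):
                    traces[(rid, cond_name, rep)] = classify_states(
                        stack_angles(series), cfg.windows
                    )
        stability = summarize_stability(traces, min_dwell=cfg.min_dwell)
        stability = stability.rename(columns={"variant": "residue_id"})

        charges = None
        if cfg.sequence_fasta:
            charges = charge_table(
                cfg.sequence_fasta, cfg.numbering_offset,
                cfg.mutations, cfg.schemes,
            )

        provenance = {
            "config_hash": _config_hash(cfg),
            "seed": cfg.seed,
            "version": __version__,
            "config": json.loads(json.dumps(asdict(cfg), default=str)),
        }
        report = Report(
            sno_table=table, sno_summary=sno_summary, selected=selected,
            stability=stability, charges=charges, provenance=provenance,
        )
        _write_artifacts(report, outdir)
        return report
    finally:
        log.removeHandler(handler)
        handler.close()


def _write_artifacts(report: Report, outdir: Path) -> None:
    # TSV at 4 significant digits for eyes, JSON at full precision
    sno_df = report.sno_table.to_frame().reset_index()
    sno_df["selected"] = sno_df["residue_id"].isin(report.selected)
    sno_df.to_csv(outdir / "report.tsv", sep="\t", index=False,
                  float_format="%.4g")
    sel = report.sno_summary[report.sno_summary["selected"]]
    sel.to_csv(outdir / "selection.tsv", sep="\t", index=False,
               float_format="%.4g")
    report.stability.to_csv(outdir / "stability.tsv", sep="\t", index=False,
                            float_format="%.4g")
    if report.charges is not None:
        report.charges.to_csv(outdir / "charges.tsv", sep="\t", index=False)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=1, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
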