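"""Readers and writers for the package's plain-text interchange formats.

Sensorgrams travel as long-format CSV (sensor_id, conc_nM, phase, t_s,
response); promoter panels as FASTA with a ground-truth sidecar TSV; fit and
scan results as TSV.  Delimited and JSON outputs carry a comment header with
the tool version, a hash of the run configuration, and the seed, so every
stochastic run is reproducible from its own output.  Concentrations are nM in
files and molar in memory.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .kinetics import Sensorgram, SensorgramSet
from .simulate import PlantedOperator, PromoterRecord

__all__ = [
    "config_hash",
    "header_lines",
    "write_sensorgram_csv",
    "read_sensorgram_csv",
    "write_panel_fasta",
    "read_fasta",
    "read_panel_truth",
    "write_kinetics_tsv",
    "write_scan_tsv",
    "write_panel_summary_tsv",
    "write_json",
]

_FLOAT_FMT = "%.12g"


def config_hash(config: dict | None) -> str:
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def header_lines(config: dict | None = None, seed: int | None = None) -> list[str]:
    lines = [f"# coperon v{__version__}", f"# config_hash: {config_hash(config)}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    return lines


def _write_frame(df: pd.DataFrame, path, sep: str, config, seed) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for line in header_lines(config, seed):
            fh.write(line + "\n")
        df.to_csv(fh, sep=sep, index=False, float_format=_FLOAT_FMT)


def write_sensorgram_csv(
    sset: SensorgramSet, path, config: dict | None = None
) -> None:
    frames = []
    for s in sset:
        frames.append(
            pd.DataFrame(
                {
                    "sensor_id": s.sensor_id,
                    "conc_nM": s.analyte_conc * 1e9,
                    "phase": s.phase,
                    "t_s": s.time,
                    "response": s.response,
                }
            )
        )
    _write_frame(pd.concat(frames, ignore_index=True), path, ",", config, sset.seed)


def read_sensorgram_csv(path) -> SensorgramSet:
    df = pd.read_csv(path, comment="#")
    required = {"sensor_id", "conc_nM", "phase", "t_s", "response"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sensorgram CSV missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError("sensorgram CSV contains no data rows")
    grams = []
    for sid, g in df.groupby("sensor_id", sort=False):
        g = g.sort_values("t_s")
        conc = float(g["conc_nM"].iloc[0]) * 1e-9
        grams.append(
            Sensorgram(
                time=g["t_s"].to_numpy(),
                response=g["response"].to_numpy(),
                phase=g["phase"].to_numpy(dtype=object),
                analyte_conc=conc,
                sensor_id=str(sid),
                is_reference=conc == 0,
            )
        )
    return SensorgramSet(sensorgrams=grams)


def write_panel_fasta(
    records: list[PromoterRecord],
    fasta_path,
    truth_path=None,
    config: dict | None = None,
    seed: int | None = None,
) -> None:
    """Write panel FASTA plus a ground-truth sidecar TSV.

    FASTA itself carries no comment header (comment lines are not part of the
    format); run metadata lives in the sidecar.
    """
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description="")
        for r in records
    ]
    SeqIO.write(seqs, str(fasta_path), "fasta")
    if truth_path is None:
        return
    rows = [
        {
            "id": r.id,
            "n_operators": r.n_operators,
            "positions": ",".join(str(o.start) for o in r.operators),
            "strands": ",".join(o.strand for o in r.operators),
            "instances": ",".join(o.instance for o in r.operators),
            "gaps": ",".join(str(g) for g in r.gaps),
        }
        for r in records
    ]
    _write_frame(pd.DataFrame(rows), truth_path, "\t", config, seed)


def read_fasta(path) -> list[PromoterRecord]:
    """Read promoters from FASTA (multi-record, wrapped lines, any case)."""
    return [
        PromoterRecord(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_panel_truth(path) -> dict[str, PromoterRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    out: dict[str, PromoterRecord] = {}
    for _, row in df.iterrows():
        ops = []
        if row["positions"]:
            for pos, strand, inst in zip(
                row["positions"].split(","),
                row["strands"].split(","),
                row["instances"].split(","),
            ):
                ops.append(PlantedOperator(int(pos), strand, inst))
        out[row["id"]] = PromoterRecord(
            id=row["id"],
            sequence="",
            operators=ops,
            gaps=[int(g) for g in row["gaps"].split(",") if g],
        )
    return out


def write_kinetics_tsv(rows: list[dict], path, config=None, seed=None) -> None:
    cols = ["construct", "k_a", "k_a_se", "k_d", "k_d_se",
            "Kd_nM", "Kd_se_nM", "R2", "call"]
    df = pd.DataFrame(rows, columns=cols)
    _write_frame(df, path, "\t", config, seed)


def write_scan_tsv(reports, pattern_label: str, path, config=None, seed=None) -> None:
    rows = [
        {
            "id": r.promoter_id,
            "pattern": pattern_label,
            "n_hits": len(r.hits),
            "count_class": r.count_class,
            "starts": ",".join(str(h.start) for h in r.collapsed),
            "strands": ",".join(h.strand for h in r.collapsed),
            "mismatches": ",".join(str(h.mismatches) for h in r.collapsed),
            "spacings": ",".join(str(g) for g in r.spacings),
            "palindromic": ",".join(str(p) for p in r.palindromic),
        }
        for r in reports
    ]
    cols = ["id", "pattern", "n_hits", "count_class", "starts", "strands",
            "mismatches", "spacings", "palindromic"]
    _write_frame(pd.DataFrame(rows, columns=cols), path, "\t", config, seed)


def write_panel_summary_tsv(summary, path, config=None, seed=None) -> None:
    rows = [
        {"metric": f"promoters_with_{k}_operators", "value": v}
        for k, v in sorted(summary.class_counts.items())
    ]
    rows.append({"metric": "n_gaps", "value": summary.spacing.n})
    rows.append({"metric": "gap_mode",
                 "value": "" if summary.spacing.mode is None else summary.spacing.mode})
    _write_frame(pd.DataFrame(rows), path, "\t", config, seed)


def write_json(payload: dict, path, config=None, seed=None) -> None:
    path = Path(path)
    meta = {
        "tool": f"coperon v{__version__}",
        "config_hash": config_hash(config),
    }
    if seed is not None:
        meta["seed"] = seed

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(type(o))

    path.write_text(json.dumps({"_meta": meta, **payload}, indent=2,
                               default=_default) + "\n")
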