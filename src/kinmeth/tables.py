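"""Plain-text tables for intermediate results (score records)."""

from __future__ import annotations

import os

import pandas as pd

from kinmeth.detection import KineticScoreRecord


def write_records(records: list[KineticScoreRecord], path: str) -> None:
    """Score records as TSV (1-based positions), in their sorted order."""
    df = pd.DataFrame([
        {
            "contig": r.contig,
            "position": r.position + 1,
            "strand": r.strand,
            "base": r.base,
            "score": round(r.score, 4),
            "n_obs": r.n_obs,
            "ipd_ratio": round(r.ipd_ratio, 6),
        }
        for r in records
    ], columns=["contig", "position", "strand", "base", "score", "n_obs", "ipd_ratio"])
    tmp = f"{path}.tmp{os.getpid()}"
    df.to_csv(tmp, sep="\t", index=False)
    os.replace(tmp, path)


def read_records(path: str) -> list[KineticScoreRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "strand": str, "base": str})
    records = [
        KineticScoreRecord(
            contig=row.contig, position=int(row.position) - 1, strand=row.strand,
            base=row.base, score=float(row.score), n_obs=int(row.n_obs),
            ipd_ratio=float(row.ipd_ratio),
        )
        for row in df.itertuples()
    ]
    records.sort(key=KineticScoreRecord.sort_key)
    return records
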