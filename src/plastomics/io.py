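"""File I/O: FASTA, GFF3, aligned FASTA, calibration tables, truth files.

GFF3 features use 1-based inclusive coordinates on disk and 0-based
half-open in memory; BED output is 0-based half-open as the format
requires. FASTA goes through Biopython.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .consolidate import RepeatFamily, RepeatSummary
from .diversity import AlignmentMatrix, CalibrationTable
from .records import Feature, FeatureSet, Interval, PlastomeRecord
from .repeats import RepeatPair
from .synthetic import SyntheticTruth


def read_fasta(path: str | Path, circular: bool = True) -> list[PlastomeRecord]:
    records = [
        PlastomeRecord(id=r.id, sequence=str(r.seq), circular=circular)
        for r in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: list[PlastomeRecord] | PlastomeRecord, path: str | Path) -> None:
    if isinstance(records, PlastomeRecord):
        records = [records]
    SeqIO.write(
        [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records],
        str(path),
        "fasta",
    )


def read_alignment(path: str | Path) -> AlignmentMatrix:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise ValueError(f"alignment {path} needs at least 2 sequences")
    return AlignmentMatrix(ids=[r.id for r in records], rows=[str(r.seq) for r in records])


def read_gff3(path: str | Path) -> FeatureSet:
    """Minimal GFF3 reader: seqid, type, start, end, strand, Name/ID."""
    feats = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(parts)}")
        _, _, ftype, start, end, _, strand, _, attrs = parts
        name = ""
        for kv in attrs.split(";"):
            if kv.startswith(("Name=", "ID=")):
                name = kv.split("=", 1)[1]
                break
        feats.append(
            Feature(
                name=name,
                interval=Interval(int(start) - 1, int(end)),
                strand=strand if strand in "+-" else "+",
                type=ftype,
            )
        )
    return FeatureSet(feats)


def write_gff3(features: FeatureSet, seqid: str, path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for f in features:
        lines.append(
            "\t".join(
                [
                    seqid,
                    "plastomics",
                    f.type,
                    str(f.interval.start + 1),
                    str(f.interval.end),
                    ".",
                    f.strand,
                    ".",
                    f"Name={f.name}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    Path(path).write_text(truth.to_yaml())


def read_truth(path: str | Path) -> SyntheticTruth:
    return SyntheticTruth.from_yaml(Path(path).read_text())


def read_calibration(path: str | Path) -> CalibrationTable:
    """TSV with columns taxon1, taxon2, years (header optional)."""
    times = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 columns")
        if lineno == 1 and parts[2].lower() in ("years", "time", "divergence_time"):
            continue
        times[(parts[0], parts[1])] = float(parts[2])
    return CalibrationTable(times)


def pairs_to_frame(pairs: list[RepeatPair]) -> pd.DataFrame:
    """Raw pair table; coordinates 1-based in file output."""
    return pd.DataFrame(
        {
            "pos1": [p.pos1 + 1 for p in pairs],
            "pos2": [p.pos2 + 1 for p in pairs],
            "length": [p.length for p in pairs],
            "orientation": [p.orientation for p in pairs],
            "mismatches": [p.mismatches for p in pairs],
        }
    )


def families_to_frame(families: list[RepeatFamily]) -> pd.DataFrame:
    rows = []
    for fam in families:
        rows.append(
            {
                "family_id": fam.family_id,
                "representative": fam.representative,
                "n_locations": fam.n_locations,
                "classification": fam.classification,
                "ir_status": fam.ir_status or "",
                "locations": ",".join(str(m.position + 1) for m in fam.members),
                "coding": ",".join(
                    "1" if c else "0" for c in (fam.coding_flags or [False] * len(fam.members))
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "family_id",
            "representative",
            "n_locations",
            "classification",
            "ir_status",
            "locations",
            "coding",
        ],
    )


def summary_to_frame(genome_id: str, summary: RepeatSummary) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": genome_id,
                "raw_pairs": summary.raw_pair_count,
                "tandem_pairs": summary.tandem_count,
                "dispersed_unique_locations": summary.dispersed_unique_locations,
                "dispersed_unique_sequences": summary.dispersed_unique_sequences,
            }
        ]
    )


def write_bed(families: list[RepeatFamily], seqid: str, path: str | Path) -> None:
    """Repeat-location track (0-based half-open), one line per member."""
    lines = []
    for fam in families:
        for m in fam.members:
            lines.append(f"{seqid}\t{m.position}\t{m.end}\t{fam.family_id}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_table(df: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    text = df.to_csv(sep="\t", index=False)
    if header_comment:
        text = f"# {header_comment}\n{text}"
    Path(path).write_text(text)


def load_yaml_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}
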