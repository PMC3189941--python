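"""Record containers and FASTA / TSV round-tripping.

FASTA parsing and writing go through Bio.SeqIO; tables through pandas. All
coordinates stored in these containers are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True)
class TranscriptRecord:
    """One assembled transcript: identifier, species tag, nucleotide string."""
    id: str
    species: str
    sequence: str


@dataclass
class TranscriptTruth:
    """Ground-truth bookkeeping for one simulated transcript."""
    transcript_id: str
    species: str
    partner_id: str | None   # the true ortholog in the other species
    cds_start: int           # on the transcript, includes the terminal stop codon
    cds_end: int
    protein_id: str          # reference protein this transcript descends from
    is_paralog: bool = False


@dataclass
class SubstitutionTruth:
    """One realized substitution on one lineage of a simulated pair."""
    pair_id: str
    lineage: str             # "A" or "B"
    position: int            # 0-based on the transcript
    ref: str                 # ancestral base at draw time
    alt: str
    region: str              # "utr5" | "cds" | "utr3"
    cpg: bool                # site was in a CG dinucleotide at draw time
    transition: bool
    synonymous: bool | None  # None outside sense codons


@dataclass
class GroundTruth:
    """Truth channel for the simulator: per-transcript and per-pair records."""
    transcripts: dict[str, TranscriptTruth] = field(default_factory=dict)
    substitutions: dict[str, list[SubstitutionTruth]] = field(default_factory=dict)

    def true_pairs(self) -> set[tuple[str, str]]:
        """Set of (id_A, id_B) true ortholog pairs (non-paralog, both present)."""
        pairs = set()
        for t in self.transcripts.values():
            if t.species == "A" and t.partner_id and not t.is_paralog:
                pairs.add((t.transcript_id, t.partner_id))
        return pairs

    def transcripts_frame(self) -> pd.DataFrame:
        rows = [asdict(t) for t in self.transcripts.values()]
        return pd.DataFrame(rows, columns=["transcript_id", "species", "partner_id",
                                           "cds_start", "cds_end", "protein_id",
                                           "is_paralog"])

    def substitutions_frame(self) -> pd.DataFrame:
        rows = [asdict(s) for pid in sorted(self.substitutions)
                for s in self.substitutions[pid]]
        return pd.DataFrame(rows, columns=["pair_id", "lineage", "position", "ref",
                                           "alt", "region", "cpg", "transition",
                                           "synonymous"])


def read_fasta(path: str | Path, species: str | None = None) -> list[TranscriptRecord]:
    """Read a FASTA file into TranscriptRecords (sequences upper-cased)."""
    species = species if species is not None else Path(path).stem
    return [TranscriptRecord(rec.id, species, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records, path: str | Path) -> None:
    """Write TranscriptRecords (or (id, seq) pairs / id->seq mapping) as FASTA."""
    if isinstance(records, dict):
        items = [(k, v) for k, v in records.items()]
    else:
        items = [(r.id, r.sequence) if isinstance(r, TranscriptRecord) else tuple(r)
                 for r in records]
    seq_records = [SeqRecord(Seq(s), id=i, description="") for i, s in items]
    SeqIO.write(seq_records, str(path), "fasta")


def as_seq_dict(records) -> dict[str, str]:
    """id -> sequence mapping from a list of TranscriptRecords."""
    if isinstance(records, dict):
        return records
    return {r.id: r.sequence for r in records}


TRUTH_COLUMNS = ["transcript_id", "species", "partner_id", "cds_start", "cds_end",
                 "protein_id", "is_paralog"]


def write_truth(truth: GroundTruth, out_dir: str | Path) -> None:
    """Write truth.tsv (per-transcript) and truth_substitutions.tsv (per-pair)."""
    out = Path(out_dir)
    truth.transcripts_frame().to_csv(out / "truth.tsv", sep="\t", index=False)
    truth.substitutions_frame().to_csv(out / "truth_substitutions.tsv",
                                       sep="\t", index=False)


def read_truth(out_dir: str | Path) -> GroundTruth:
    out = Path(out_dir)
    gt = GroundTruth()
    tdf = pd.read_csv(out / "truth.tsv", sep="\t",
                      dtype={"partner_id": "string"})
    for row in tdf.itertuples(index=False):
        partner = None if pd.isna(row.partner_id) else str(row.partner_id)
        gt.transcripts[row.transcript_id] = TranscriptTruth(
            row.transcript_id, row.species, partner,
            int(row.cds_start), int(row.cds_end), row.protein_id,
            bool(row.is_paralog))
    spath = out / "truth_substitutions.tsv"
    if spath.exists():
        sdf = pd.read_csv(spath, sep="\t")
        for row in sdf.itertuples(index=False):
            syn = None if pd.isna(row.synonymous) else bool(row.synonymous)
            gt.substitutions.setdefault(row.pair_id, []).append(SubstitutionTruth(
                row.pair_id, row.lineage, int(row.position), row.ref, row.alt,
                row.region, bool(row.cpg), bool(row.transition), syn))
    return gt
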