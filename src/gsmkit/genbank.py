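"""Genome input: GenBank CDS extraction and FASTA helpers (Biopython-backed)."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)


@dataclass
class CDSRecord:
    locus_tag: str
    cds: str          # nucleotide coding sequence (5'->3')
    protein: str      # translated product, stop codon dropped
    partial: bool     # length not divisible by three
    product: Optional[str] = None


def translate_cds(nucleotides: str) -> str:
    """Standard-table translation, trailing stop removed."""
    usable = len(nucleotides) - len(nucleotides) % 3
    protein = str(Seq(nucleotides[:usable]).translate(table=1))
    return protein.rstrip("*")


def read_genbank_cds(path) -> List[CDSRecord]:
    """Extract one record per CDS feature of a GenBank flat file.

    The file's own ``/translation`` qualifier is trusted when present;
    otherwise the CDS is translated with the standard code.  A CDS whose
    length is not a multiple of three is flagged partial.
    """
    records: List[CDSRecord] = []
    for seq_record in SeqIO.parse(str(path), "genbank"):
        for feature in seq_record.features:
            if feature.type != "CDS":
                continue
            quals = feature.qualifiers
            locus_tag = quals.get("locus_tag", [None])[0]
            if locus_tag is None:
                logger.warning("CDS without locus_tag skipped at %s", feature.location)
                continue
            cds = str(feature.extract(seq_record.seq))
            partial = len(cds) % 3 != 0
            if "translation" in quals:
                protein = quals["translation"][0]
            else:
                protein = translate_cds(cds)
            records.append(
                CDSRecord(
                    locus_tag=locus_tag,
                    cds=cds,
                    protein=protein,
                    partial=partial,
                    product=quals.get("product", [None])[0],
                )
            )
    if not records:
        warnings.warn(f"{path}: no CDS features found", stacklevel=2)
    return records


def read_fasta(path) -> Dict[str, str]:
    """FASTA file -> {record id: sequence}."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


__all__ = ["CDSRecord", "read_genbank_cds", "read_fasta", "write_fasta", "translate_cds"]
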