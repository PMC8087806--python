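"""Reference amplicon: the sequenced target and its candidate editing positions.

A-to-I editing is read out as A→G mismatches on the sense strand, so the only
positions of interest are reference adenosines.  The amplicon model is a plain
sequence plus an ordered map of labelled candidate A positions (letters A..N,
following the field convention of naming sites within an editing island by
letters in genomic order).

The default amplicon shipped here is a *synthetic* 225-bp stand-in: the real
intronic sequence is not redistributed, and nothing downstream depends on the
nucleotide context — only on the labelled A positions.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DEFAULT_LENGTH = 225

#: 0-based offsets of the 14 candidate A positions (labels A..N in order).
DEFAULT_SITE_OFFSETS = (
    12, 27, 41, 56, 70, 85, 99, 114, 128, 143, 157, 172, 186, 201,
)


@dataclass(frozen=True)
class CandidateSite:
    """A labelled candidate editing position (reference base must be A)."""

    label: str
    offset: int  # 0-based position in the amplicon


@dataclass(frozen=True)
class ReferenceAmplicon:
    """Target sequence plus labelled candidate A positions.

    Invariants (checked at construction): offsets are unique, strictly
    increasing and in bounds; the reference base at every candidate offset
    is 'A'.
    """

    name: str
    sequence: str
    sites: tuple[CandidateSite, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if set(seq) - set("ACGTN"):
            raise ValueError("sequence contains non-nucleotide characters")
        offsets = [s.offset for s in self.sites]
        if offsets != sorted(set(offsets)):
            raise ValueError("candidate offsets must be unique and strictly increasing")
        for s in self.sites:
            if not 0 <= s.offset < len(seq):
                raise ValueError(f"site {s.label}: offset {s.offset} out of bounds")
            if seq[s.offset] != "A":
                raise ValueError(
                    f"site {s.label}: reference base at offset {s.offset} is "
                    f"{seq[s.offset]!r}, must be 'A'"
                )
        labels = [s.label for s in self.sites]
        if len(set(labels)) != len(labels):
            raise ValueError("site labels must be unique")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.sites]

    @property
    def offsets(self) -> np.ndarray:
        return np.array([s.offset for s in self.sites], dtype=np.intp)

    def offset_of(self, label: str) -> int:
        for s in self.sites:
            if s.label == label:
                return s.offset
        raise KeyError(f"unknown site label {label!r}")

    def encoded(self) -> np.ndarray:
        """Sequence as uint8 ASCII codes (for vectorised comparison)."""
        return np.frombuffer(self.sequence.encode("ascii"), dtype=np.uint8).copy()


def default_amplicon(seed: int = 7) -> ReferenceAmplicon:
    """Synthetic 225-bp amplicon with 14 candidate A positions labelled A..N.

    A deterministic stand-in for the real editing-island target, which is not
    redistributed here.  The sequence is drawn once from a fixed seed and
    forced to 'A' at the candidate offsets.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=DEFAULT_LENGTH)
    seq[list(DEFAULT_SITE_OFFSETS)] = "A"
    sites = tuple(
        CandidateSite(label=string.ascii_uppercase[i], offset=off)
        for i, off in enumerate(DEFAULT_SITE_OFFSETS)
    )
    return ReferenceAmplicon(
        name="editing_island_amplicon_synthetic",
        sequence="".join(seq),
        sites=sites,
    )


def write_reference(ref: ReferenceAmplicon, fasta_path: str | Path, sites_path: str | Path) -> None:
    """Write the amplicon as FASTA plus a site-map TSV (label, 1-based pos, ref base)."""
    rec = SeqRecord(Seq(ref.sequence), id=ref.name, description="")
    SeqIO.write([rec], str(fasta_path), "fasta")
    pd.DataFrame(
        {
            "label": ref.labels,
            "position": [s.offset + 1 for s in ref.sites],  # 1-based in exports
            "ref_base": ["A"] * len(ref.sites),
        }
    ).to_csv(sites_path, sep="\t", index=False)


def read_reference(fasta_path: str | Path, sites_path: str | Path) -> ReferenceAmplicon:
    """Load an amplicon from FASTA + site-map TSV (positions 1-based)."""
    rec = next(SeqIO.parse(str(fasta_path), "fasta"))
    sites_df = pd.read_csv(sites_path, sep="\t")
    sites = tuple(
        CandidateSite(label=str(row.label), offset=int(row.position) - 1)
        for row in sites_df.itertuples()
    )
    return ReferenceAmplicon(name=rec.id, sequence=str(rec.seq), sites=sites)
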