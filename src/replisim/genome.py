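"""Genome specification: chromosome lengths, centromeres, chromosome-12 split.

The budding-yeast genome is modeled at 1 kb per monomer.  Sixteen
chromosomes give 17 polymer chains: chromosome 12 is split at 460 kb into a
centromere-carrying chain A (ending in an rDNA-boundary monomer) and a
centromere-free chain B (starting with the second rDNA boundary), with the
nucleolus standing in for the rDNA repeats themselves.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kernels import ROLE_CEN, ROLE_RDNA, ROLE_TELO

RDNA_SPLIT_KB = 460
RDNA_CHROM = "chrXII"


@dataclass(frozen=True)
class Chain:
    name: str
    chrom: str
    chrom_index: int
    length: int                 # monomers (kb)
    offset_kb: int              # genomic start of the chain on its chromosome
    centromere: int | None      # local monomer index, None for chain B
    rdna_first: bool
    rdna_last: bool


class GenomeSpec:
    """Chromosome table plus the derived 17-chain layout.

    Global bins are the chains concatenated in genomic order, so bin order
    equals genomic order genome-wide (the two chromosome-12 chains are
    adjacent and in sequence).
    """

    def __init__(self, table: pd.DataFrame, split_kb: int = RDNA_SPLIT_KB):
        required = {"chrom", "length_kb", "centromere_kb"}
        if not required.issubset(table.columns):
            raise ValueError(f"genome table needs columns {sorted(required)}")
        self.table = table.reset_index(drop=True)
        self.chroms = list(self.table["chrom"])
        lengths = self.table["length_kb"].to_numpy(int)
        cens = self.table["centromere_kb"].to_numpy(int)
        if (lengths <= 0).any():
            raise ValueError("chromosome lengths must be positive")
        if ((cens < 0) | (cens >= lengths)).any():
            raise ValueError("centromere outside chromosome")
        self.split_kb = int(split_kb)

        chains: list[Chain] = []
        for i, (name, ln, cen) in enumerate(zip(self.chroms, lengths, cens)):
            if name == RDNA_CHROM:
                if not (0 < self.split_kb < ln and cen < self.split_kb):
                    raise ValueError("invalid chromosome-12 split")
                chains.append(Chain(f"{name}_A", name, i, self.split_kb, 0,
                                    int(cen), False, True))
                chains.append(Chain(f"{name}_B", name, i, ln - self.split_kb,
                                    self.split_kb, None, True, False))
            else:
                chains.append(Chain(name, name, i, int(ln), 0, int(cen),
                                    False, False))
        self.chains = chains
        self.n_chains = len(chains)

        self.chain_first = np.zeros(self.n_chains, dtype=np.int64)
        self.chain_last = np.zeros(self.n_chains, dtype=np.int64)
        off = 0
        for ci, ch in enumerate(chains):
            self.chain_first[ci] = off
            self.chain_last[ci] = off + ch.length - 1
            off += ch.length
        self.n_monomers = off
        self.bin_chain = np.zeros(self.n_monomers, dtype=np.int64)
        self.bin_chrom = np.zeros(self.n_monomers, dtype=np.int64)
        self.bin_start_kb = np.zeros(self.n_monomers, dtype=np.int64)
        self.roles = np.zeros(self.n_monomers, dtype=np.uint8)
        for ci, ch in enumerate(chains):
            b0, b1 = self.chain_first[ci], self.chain_last[ci]
            sl = slice(b0, b1 + 1)
            self.bin_chain[sl] = ci
            self.bin_chrom[sl] = ch.chrom_index
            self.bin_start_kb[sl] = ch.offset_kb + np.arange(ch.length)
            if ch.centromere is not None:
                self.roles[b0 + ch.centromere] |= ROLE_CEN
            # true chromosome ends are telomeres; rDNA boundaries are not
            if not ch.rdna_first:
                self.roles[b0] |= ROLE_TELO
            else:
                self.roles[b0] |= ROLE_RDNA
            if not ch.rdna_last:
                self.roles[b1] |= ROLE_TELO
            else:
                self.roles[b1] |= ROLE_RDNA

    # ------------------------------------------------------------------
    @classmethod
    def builtin(cls) -> "GenomeSpec":
        """The packaged S. cerevisiae (sacCer3) genome table."""
        ref = importlib.resources.files("replisim.data") / "sc_genome.tsv"
        with importlib.resources.as_file(ref) as path:
            return cls.from_tsv(path)

    @classmethod
    def from_tsv(cls, path) -> "GenomeSpec":
        table = pd.read_csv(path, sep="\t", comment="#",
                            names=["chrom", "length_kb", "centromere_kb"])
        return cls(table)

    @classmethod
    def toy(cls, lengths, centromeres=None, names=None) -> "GenomeSpec":
        """Small artificial genomes for tests and scaled-down experiments."""
        lengths = list(lengths)
        if centromeres is None:
            centromeres = [ln // 2 for ln in lengths]
        if names is None:
            names = [f"toy{i + 1}" for i in range(len(lengths))]
        return cls(pd.DataFrame({"chrom": names, "length_kb": lengths,
                                 "centromere_kb": centromeres}))

    # ------------------------------------------------------------------
    @property
    def chromosome_lengths(self) -> dict[str, int]:
        return dict(zip(self.chroms, self.table["length_kb"].to_numpy(int)))

    def centromere_bins(self) -> np.ndarray:
        return np.flatnonzero(self.roles & ROLE_CEN)

    def telomere_bins(self) -> np.ndarray:
        return np.flatnonzero(self.roles & ROLE_TELO)

    def rdna_bins(self) -> np.ndarray:
        return np.flatnonzero(self.roles & ROLE_RDNA)

    def chrom_of_bin(self, b) -> str:
        return self.chroms[int(self.bin_chrom[b])]

    def bin_table(self, resolution_kb: int = 1) -> pd.DataFrame:
        """Cooler-style bin table (chrom, start, end) at a multiple of 1 kb."""
        rows = []
        for name, ln in self.chromosome_lengths.items():
            starts = np.arange(0, ln, resolution_kb)
            ends = np.minimum(starts + resolution_kb, ln)
            rows.append(pd.DataFrame({"chrom": name,
                                      "start": starts * 1000,
                                      "end": ends * 1000}))
        return pd.concat(rows, ignore_index=True)
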