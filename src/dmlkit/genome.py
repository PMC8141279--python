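"""Synthetic genome model: chromosomes, CpG positions, optional sequence.

The genome stands in for a reference assembly at desk scale.  CpG positions are
1-based (the convention of cytosine reports); interval work elsewhere in the
package is 0-based half-open, and conversion happens at module boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._streams import substream

__all__ = ["GenomeModel", "build_genome", "extract_window", "gc_fraction", "write_fasta", "read_fasta"]

_BASES = np.array(list("ACGT"))


@dataclass
class GenomeModel:
    """Chromosome sizes, CpG positions and (optionally) nucleotide sequence.

    ``cpg_positions[chrom]`` holds sorted, strictly increasing 1-based positions
    of the C of each CpG dyad; if ``sequence`` is present it carries a ``CG``
    dinucleotide at every listed position.
    """

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    cpg_positions: dict[str, np.ndarray]
    sequence: dict[str, str] | None = field(default=None, repr=False)

    def validate(self) -> None:
        for chrom in self.chrom_names:
            length = self.chrom_lengths[chrom]
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length {length}")
            pos = np.asarray(self.cpg_positions[chrom])
            if pos.size and (np.any(np.diff(pos) <= 0) or pos[0] < 1 or pos[-1] > length - 1):
                raise ValueError(f"CpG positions on {chrom} not strictly increasing within [1, L-1]")
            if self.sequence is not None:
                seq = self.sequence[chrom]
                if len(seq) != length:
                    raise ValueError(f"sequence length mismatch on {chrom}")
                for p in pos:
                    if seq[p - 1 : p + 1] != "CG":
                        raise ValueError(f"no CG dinucleotide at {chrom}:{p}")

    @property
    def n_cpgs(self) -> int:
        return int(sum(len(p) for p in self.cpg_positions.values()))

    def total_length(self) -> int:
        return int(sum(self.chrom_lengths.values()))


def build_genome(
    n_chroms: int,
    chrom_length_bp: int,
    cpg_density: float,
    seed: int,
    with_sequence: bool = False,
) -> GenomeModel:
    """Simulate a genome with Bernoulli-placed CpG dyads.

    Each eligible base (1..L-1) becomes the C of a CpG with probability
    ``cpg_density``; picks closer than 2 bp are thinned so dyads never overlap.
    With ``with_sequence`` a random background sequence is drawn and ``CG``
    written at every CpG position.
    """
    if n_chroms <= 0 or chrom_length_bp < 10_000:
        raise ValueError("need n_chroms >= 1 and chrom_length_bp >= 10000")
    if not 0 < cpg_density <= 0.1:
        raise ValueError("cpg_density must be in (0, 0.1]")
    rng = substream(seed, "genome")
    names = [f"chr{i + 1}" for i in range(n_chroms)]
    lengths = {c: int(chrom_length_bp) for c in names}
    positions: dict[str, np.ndarray] = {}
    sequence: dict[str, str] | None = {} if with_sequence else None
    for chrom in names:
        draw = rng.random(chrom_length_bp - 1) < cpg_density
        pos = np.flatnonzero(draw) + 1  # 1-based
        if pos.size > 1:
            # sequential thinning: keep a position only if >=2 bp after the last kept one
            kept = []
            last = -10
            for p in pos:
                if p - last >= 2:
                    kept.append(p)
                    last = p
            pos = np.asarray(kept, dtype=np.int64)
        positions[chrom] = pos.astype(np.int64)
        if with_sequence:
            seq = rng.choice(_BASES, size=chrom_length_bp)
            seq[pos - 1] = "C"
            seq[pos] = "G"
            sequence[chrom] = "".join(seq)
    model = GenomeModel(names, lengths, positions, sequence)
    model.validate()
    return model


def extract_window(genome: GenomeModel, chrom: str, center: int, flank: int) -> tuple[int, int, str]:
    """Return (start0, end0, seq) for the window ±flank around a 1-based point,
    truncated at chromosome edges."""
    if genome.sequence is None:
        raise ValueError("genome carries no sequence")
    length = genome.chrom_lengths[chrom]
    start = max(0, center - 1 - flank)
    end = min(length, center - 1 + flank)
    return start, end, genome.sequence[chrom][start:end]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def write_fasta(genome: GenomeModel, path) -> None:
    if genome.sequence is None:
        raise ValueError("genome carries no sequence")
    with open(path, "w") as fh:
        for chrom in genome.chrom_names:
            fh.write(f">{chrom}\n")
            seq = genome.sequence[chrom]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_fasta(path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None:
                seqs[name].append(line)
    return {k: "".join(v) for k, v in seqs.items()}
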