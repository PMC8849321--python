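"""In-memory genome sequences with plain-text FASTA I/O."""

from __future__ import annotations

from typing import Dict, Iterator

from .errors import UsageError

__all__ = ["Genome", "reverse_complement"]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class Genome:
    """A set of named chromosome sequences (uppercase strings)."""

    def __init__(self, seqs: Dict[str, str]):
        if not seqs:
            raise UsageError("genome must contain at least one chromosome")
        self._seqs = {name: seq.upper() for name, seq in seqs.items()}

    @property
    def sizes(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self._seqs.items()}

    def chroms(self) -> Iterator[str]:
        return iter(self._seqs)

    def sequence(self, chrom: str) -> str:
        return self._seqs[chrom]

    def base_composition(self) -> "np.ndarray":
        """Genome-wide (A, C, G, T) frequencies, ignoring other characters."""
        import numpy as np

        counts = np.zeros(4)
        for seq in self._seqs.values():
            for i, b in enumerate("ACGT"):
                counts[i] += seq.count(b)
        if counts.sum() == 0:
            raise UsageError("genome contains no ACGT bases")
        return counts / counts.sum()

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of ``chrom:[start, end)``; raises on out-of-range."""
        seq = self._seqs[chrom]
        if not (0 <= start < end <= len(seq)):
            raise UsageError(
                f"fetch {chrom}:{start}-{end} outside chromosome of length {len(seq)}"
            )
        return seq[start:end]

    # -- FASTA --------------------------------------------------------------
    def write_fasta(self, path, line_width: int = 60) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i : i + line_width] + "\n")

    @classmethod
    def read_fasta(cls, path) -> "Genome":
        seqs: Dict[str, list] = {}
        current = None
        with open(path) as fh:
            for line in fh:
                line = line.rstrip()
                if not line:
                    continue
                if line.startswith(">"):
                    current = line[1:].split()[0]
                    seqs[current] = []
                else:
                    if current is None:
                        raise UsageError(f"{path}: sequence before first FASTA header")
                    seqs[current].append(line)
        return cls({name: "".join(parts) for name, parts in seqs.items()})
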