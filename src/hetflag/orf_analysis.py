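"""Longest-ORF detection and a Monte-Carlo null for ORF length by chance.

An ORF is an ATG followed by an in-frame stop codon (TAA/TAG/TGA) on the
sense strand; its length runs from the A of the ATG through the last base
of the stop codon inclusive, so lengths are multiples of 3 and at least 6.
Codons containing N never match ATG or a stop.  A transcript is
single-stranded, so only the three sense frames are scanned.

The chance model asks how long an ORF one should expect in a random
transcript of the same length and base composition: replicate sequences
are drawn i.i.d. from the (default: observed mononucleotide) composition,
and the empirical p-value for an observed longest-ORF length is
(1 + #{replicates ≥ observed}) / (reps + 1).  A dinucleotide-preserving
shuffle of a reference sequence is available as an alternative null.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
from Bio import SeqIO

from .errors import ConfigError, HetflagError

START_CODON = "ATG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_VALID = frozenset("ACGTN")


@dataclass(frozen=True)
class OrfHit:
    """One open reading frame: [start, end) on the sense strand."""

    start: int
    end: int
    frame: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class OrfNullResult:
    observed_length: int
    replicate_lengths: np.ndarray
    p_value: float
    reps: int
    seed: int | None
    composition: Mapping[str, float]


def _validate(sequence: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - _VALID
    if bad:
        raise HetflagError(f"invalid nucleotide characters: {sorted(bad)}")
    return seq


def longest_orf(sequence: str) -> OrfHit | None:
    """Longest complete ORF over the three sense frames, ties broken by
    smallest start; the stop codon is inside [start, end).  Use
    :func:`orf_length` with ``include_stop=False`` for the
    stop-codon-excluded length convention."""
    seq = _validate(sequence)
    best: OrfHit | None = None
    for frame in range(3):
        open_start = -1  # earliest ATG since the last stop in this frame
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos:pos + 3]
            if codon in STOP_CODONS:
                if open_start >= 0:
                    hit = OrfHit(open_start, pos + 3, frame)
                    if best is None or hit.length > best.length or (
                            hit.length == best.length and hit.start < best.start):
                        best = hit
                    open_start = -1
            elif codon == START_CODON and open_start < 0:
                open_start = pos
    return best


def orf_length(hit: OrfHit | None, include_stop: bool = True) -> int:
    """Length in nt of a hit (0 for none); optionally without the stop."""
    if hit is None:
        return 0
    return hit.length if include_stop else hit.length - 3


def composition_of(sequence: str) -> dict[str, float]:
    """Mononucleotide frequencies over A/C/G/T (N excluded)."""
    seq = _validate(sequence)
    counts = {b: seq.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise HetflagError("sequence contains no unambiguous bases")
    return {b: c / total for b, c in counts.items()}


def orf_chance_pvalue(observed_length: int, transcript_length: int,
                      composition: Mapping[str, float] | None = None,
                      reps: int = 1000, seed: int | None = None) -> OrfNullResult:
    """Monte-Carlo p-value for a longest ORF of ``observed_length`` nt in a
    random transcript of ``transcript_length`` nt.

    Uses the add-one-corrected empirical p-value, so p is never 0 and its
    minimum is 1/(reps+1).
    """
    if reps < 100:
        raise ConfigError("need at least 100 replicates")
    if transcript_length < 6:
        raise ConfigError("transcript_length must be at least 6")
    if composition is None:
        composition = {b: 0.25 for b in "ACGT"}
    bases = np.array(list("ACGT"))
    probs = np.array([composition.get(b, 0.0) for b in "ACGT"], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
        raise ConfigError("composition must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    lengths = np.empty(reps, dtype=int)
    for r in range(reps):
        seq = "".join(rng.choice(bases, size=transcript_length, p=probs))
        lengths[r] = orf_length(longest_orf(seq))
    exceed = int((lengths >= observed_length).sum())
    return OrfNullResult(
        observed_length=observed_length,
        replicate_lengths=lengths,
        p_value=(1 + exceed) / (reps + 1),
        reps=reps, seed=seed, composition=dict(composition),
    )


def dinucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Random shuffle preserving exact dinucleotide counts
    (Altschul–Erickson: random Eulerian walk on the dinucleotide graph)."""
    seq = _validate(sequence)
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    # pick a random "last edge" per vertex whose target can still reach the
    # terminal vertex; retry until the last-edge set forms a tree into `last`
    for _ in range(10_000):
        trial = {v: rng.integers(len(out)) for v, out in edges.items()}
        ok = True
        for v in edges:
            if v == last:
                continue
            seen, cur = {v}, edges[v][trial[v]]
            while cur != last and cur in edges:
                if cur in seen:
                    ok = False
                    break
                seen.add(cur)
                cur = edges[cur][trial[cur]]
            if not ok or (cur != last and cur not in edges):
                ok = False
                break
        if ok:
            break
    else:  # pragma: no cover - practically unreachable
        raise HetflagError("dinucleotide shuffle failed to find an Eulerian walk")
    shuffled_edges = {}
    for v, out in edges.items():
        idx = list(range(len(out)))
        last_i = int(trial[v])
        rest = [i for i in idx if i != last_i]
        rng.shuffle(rest)
        shuffled_edges[v] = [out[i] for i in rest] + [out[last_i]]
    walk = [seq[0]]
    ptr = {v: 0 for v in edges}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled_edges[cur][ptr[cur]]
        ptr[cur] += 1
        walk.append(nxt)
        cur = nxt
    return "".join(walk)


def orf_chance_pvalue_dinuc(sequence: str, observed_length: int | None = None,
                            reps: int = 1000, seed: int | None = None) -> OrfNullResult:
    """As :func:`orf_chance_pvalue` but with a dinucleotide-preserving
    shuffle of ``sequence`` as the null."""
    if reps < 100:
        raise ConfigError("need at least 100 replicates")
    seq = _validate(sequence)
    if observed_length is None:
        observed_length = orf_length(longest_orf(seq))
    rng = np.random.default_rng(seed)
    lengths = np.array([
        orf_length(longest_orf(dinucleotide_shuffle(seq, rng))) for _ in range(reps)
    ])
    exceed = int((lengths >= observed_length).sum())
    return OrfNullResult(observed_length, lengths, (1 + exceed) / (reps + 1),
                         reps, seed, composition_of(seq))


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (record id, uppercase sequence) pairs from a FASTA file."""
    for rec in SeqIO.parse(str(path), "fasta"):
        yield rec.id, str(rec.seq).upper()
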