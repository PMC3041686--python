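"""Aligned sequence sets, clone metadata, and haplotype collapsing.

The sequence substrate for the distance and AMOVA analyses is an aligned
multi-FASTA of ribosomal DNA (one record per clone) plus a delimited
metadata table mapping each clone to its collection population and,
optionally, a phylogenetic group label.  Identical sequences are collapsed
into haplotypes either by exact string identity (``strict``) or ignoring
columns where either sequence carries a gap or ambiguous base
(``ignore_gapN``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGT")
ALPHABET = frozenset("ACGTN-")

AmbiguousPolicy = Literal["strict", "ignore_gapN"]


class AlignmentError(ValueError):
    """Raised for malformed alignments (ragged records, duplicate ids)."""


@dataclass(frozen=True)
class CloneMetadata:
    """Collection metadata for one clone."""

    clone_id: str
    population: str
    group: str | None = None


@dataclass
class AlignedSequenceSet:
    """Named, equal-length nucleotide sequences with optional metadata.

    Sequences are stored upper-case over the alphabet {A, C, G, T, N, -};
    ``U`` is mapped to ``T`` on construction.
    """

    ids: list[str]
    sequences: list[str]
    metadata: dict[str, CloneMetadata] = field(default_factory=dict)
    unmatched_metadata: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise AlignmentError("ids and sequences differ in number")
        seen: set[str] = set()
        for name in self.ids:
            if name in seen:
                raise AlignmentError(f"duplicate sequence id: {name!r}")
            seen.add(name)
        cleaned = []
        for name, s in zip(self.ids, self.sequences):
            s = s.upper().replace("U", "T")
            bad = set(s) - ALPHABET
            if bad:
                raise AlignmentError(
                    f"record {name!r} contains invalid characters: {sorted(bad)}"
                )
            cleaned.append(s)
        if cleaned:
            n = len(cleaned[0])
            for name, s in zip(self.ids, cleaned):
                if len(s) != n:
                    raise AlignmentError(
                        f"record {name!r} has length {len(s)}, expected {n}: "
                        "alignment is ragged"
                    )
        self.sequences = cleaned

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.sequences[0]) if self.sequences else 0

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(zip(self.ids, self.sequences))

    def sequence(self, name: str) -> str:
        return self.sequences[self.ids.index(name)]

    def populations(self) -> dict[str, str]:
        """Map of clone id -> population for every record with metadata."""
        return {
            i: self.metadata[i].population for i in self.ids if i in self.metadata
        }

    def groups(self) -> dict[str, str]:
        """Map of clone id -> group for records whose metadata has a group."""
        out = {}
        for i in self.ids:
            m = self.metadata.get(i)
            if m is not None and m.group is not None:
                out[i] = m.group
        return out

    def subset(self, names: Iterable[str]) -> "AlignedSequenceSet":
        names = list(names)
        idx = {n: self.ids.index(n) for n in names}
        return AlignedSequenceSet(
            ids=names,
            sequences=[self.sequences[idx[n]] for n in names],
            metadata={n: self.metadata[n] for n in names if n in self.metadata},
        )

    def slice_columns(self, start: int, end: int) -> "AlignedSequenceSet":
        """Extract an alignment window, 1-based inclusive on both ends."""
        if not (1 <= start <= end <= self.length):
            raise AlignmentError(
                f"window [{start}, {end}] outside alignment of length {self.length}"
            )
        return AlignedSequenceSet(
            ids=list(self.ids),
            sequences=[s[start - 1 : end] for s in self.sequences],
            metadata=dict(self.metadata),
        )


@dataclass
class HaplotypeSet:
    """A partition of clone ids into identical-sequence classes.

    ``haplotypes`` maps the representative sequence of each class to the
    sorted list of member ids.  The representative is the sequence of the
    lexicographically smallest member id, which makes the collapse
    deterministic.
    """

    haplotypes: list[tuple[str, list[str]]]
    n_clones: int

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def membership(self) -> dict[str, int]:
        """Clone id -> haplotype index."""
        out = {}
        for k, (_, members) in enumerate(self.haplotypes):
            for m in members:
                out[m] = k
        return out

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"haplotype": f"H{k + 1:03d}", "clone_id": m}
            for k, (_, members) in enumerate(self.haplotypes)
            for m in members
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> dict[str, CloneMetadata]:
    """Read a clone metadata table (TSV with header: clone_id, population[, group])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"clone_id", "population"}
    missing = required - set(df.columns)
    if missing:
        raise AlignmentError(f"metadata table missing columns: {sorted(missing)}")
    out: dict[str, CloneMetadata] = {}
    for _, row in df.iterrows():
        cid = row["clone_id"]
        if cid in out:
            raise AlignmentError(f"duplicate metadata row for clone {cid!r}")
        group = row.get("group")
        if pd.isna(group):
            group = None
        out[cid] = CloneMetadata(clone_id=cid, population=row["population"], group=group)
    return out


def read_alignment(
    path: str | Path, metadata_path: str | Path | None = None
) -> AlignedSequenceSet:
    """Read an aligned multi-FASTA, optionally joining a metadata table by id.

    Metadata rows whose clone_id matches no sequence are collected in
    ``unmatched_metadata`` rather than raising, so a roster covering more
    clones than were sequenced can be reused.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    seqs = AlignedSequenceSet(
        ids=[r.id for r in records], sequences=[str(r.seq) for r in records]
    )
    if metadata_path is not None:
        meta = read_metadata(metadata_path)
        present = set(seqs.ids)
        seqs.metadata = {k: v for k, v in meta.items() if k in present}
        seqs.unmatched_metadata = sorted(set(meta) - present)
    return seqs


def write_alignment(seqs: AlignedSequenceSet, path: str | Path) -> None:
    """Write the set as multi-FASTA (sequences round-trip byte-identically)."""
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


def _compatible(a: str, b: str) -> bool:
    # identical wherever both columns are unambiguous bases
    return all(
        ca == cb or ca not in VALID_BASES or cb not in VALID_BASES
        for ca, cb in zip(a, b)
    )


def collapse_haplotypes(
    seqs: AlignedSequenceSet, ambiguous_policy: AmbiguousPolicy = "ignore_gapN"
) -> HaplotypeSet:
    """Collapse identical sequences into haplotypes.

    Under ``strict`` two clones share a haplotype iff their aligned strings
    are identical.  Under ``ignore_gapN`` they do iff they agree at every
    column where both carry an unambiguous base; because that relation is
    not transitive, haplotypes are its connected components (single
    linkage), so a fully ambiguous sequence can bridge otherwise distinct
    haplotypes.
    """
    if len(seqs) == 0:
        raise AlignmentError("cannot collapse an empty sequence set")
    if ambiguous_policy not in ("strict", "ignore_gapN"):
        raise ValueError(f"unknown ambiguous_policy: {ambiguous_policy!r}")

    order = sorted(range(len(seqs)), key=lambda k: seqs.ids[k])
    if ambiguous_policy == "strict":
        classes: dict[str, list[str]] = {}
        for k in order:
            classes.setdefault(seqs.sequences[k], []).append(seqs.ids[k])
        haplos = [(s, members) for s, members in classes.items()]
    else:
        # union-find over the pairwise compatibility relation
        parent = list(range(len(seqs)))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for ai in range(len(order)):
            for bi in range(ai + 1, len(order)):
                i, j = order[ai], order[bi]
                ri, rj = find(i), find(j)
                if ri != rj and _compatible(seqs.sequences[i], seqs.sequences[j]):
                    parent[rj] = ri
        comps: dict[int, list[str]] = {}
        for k in order:
            comps.setdefault(find(k), []).append(seqs.ids[k])
        haplos = []
        for members in comps.values():
            rep = seqs.sequence(min(members))
            haplos.append((rep, members))

    haplos.sort(key=lambda h: min(h[1]))
    return HaplotypeSet(
        haplotypes=[(s, sorted(m)) for s, m in haplos], n_clones=len(seqs)
    )
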