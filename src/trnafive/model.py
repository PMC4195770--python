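"""tRNA gene models, cloverleaf annotation and structural coordinates.

Every downstream stage of the pipeline aggregates signal across a family
of highly similar tRNA genes.  Because the genes differ in length (D-loop
and variable-loop size vary), positions are compared in a structural
coordinate system rather than in raw sequence space: each nucleotide of a
gene is mapped to a canonical label 1..76, with the first paired
nucleoside of the T-arm (TPsiC) stem fixed at position 49 and the variable
loop numbered backwards from 48.  Type II tRNAs with long variable loops
receive insertion labels 47a, 47b, ...

Sequential indices are 0-based half-open internally and 1-based in all
exported tables.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "StructuralLabel",
    "ArmAnnotation",
    "TRNAGene",
    "annotate_cloverleaf",
    "assign_structural_numbering",
    "has_cytosine_at",
    "group_genes",
    "pair_map",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: base pairs accepted when validating supplied structures (WC + GU wobble)
VALID_PAIRS = {"AT", "TA", "GC", "CG", "GT", "TG"}


def normalize_seq(seq: str) -> str:
    """Uppercase and convert RNA (U) to the internal DNA alphabet."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=False)
class StructuralLabel:
    """Canonical tRNA coordinate: an integer 1..76 plus an optional
    insertion letter used for expansions (e.g. 47a, 47b in the variable
    loop of type II tRNAs)."""

    number: int
    insertion: str = ""

    def __post_init__(self):
        if not (1 <= self.number <= 76):
            raise ValueError(f"structural number out of range: {self.number}")
        if self.insertion and self.insertion not in string.ascii_lowercase:
            raise ValueError(f"bad insertion suffix: {self.insertion!r}")

    def __str__(self) -> str:
        return f"{self.number}{self.insertion}"

    def __repr__(self) -> str:
        return f"StructuralLabel({self})"

    @property
    def sort_key(self) -> tuple[int, str]:
        return (self.number, self.insertion)

    def __lt__(self, other: "StructuralLabel") -> bool:
        return self.sort_key < other.sort_key

    def __le__(self, other: "StructuralLabel") -> bool:
        return self.sort_key <= other.sort_key

    @classmethod
    def parse(cls, text: str | int) -> "StructuralLabel":
        if isinstance(text, StructuralLabel):
            return text
        if isinstance(text, int):
            return cls(text)
        text = str(text).strip()
        num = text.rstrip(string.ascii_lowercase)
        return cls(int(num), text[len(num):])


def _sl(number: int, insertion: str = "") -> StructuralLabel:
    return StructuralLabel(number, insertion)


def pair_map(dot_bracket: str) -> dict[int, int]:
    """Base-pair table of a dot-bracket string (both directions)."""
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for i, c in enumerate(dot_bracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket structure")
            j = stack.pop()
            pairs[i] = j
            pairs[j] = i
        elif c != ".":
            raise ValueError(f"invalid structure character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket structure")
    return pairs


# region names, 5' to 3'.  Empty regions are kept as zero-width intervals so
# that the intervals always tile the sequence.
REGIONS = (
    "acceptor_stem_5p",
    "linker_ad",          # canonical positions 8-9
    "d_stem_5p",
    "d_loop",
    "d_stem_3p",
    "linker_da",          # canonical position 26
    "anticodon_stem_5p",
    "anticodon_loop",
    "anticodon_stem_3p",
    "variable_loop",
    "t_stem_5p",
    "t_loop",
    "t_stem_3p",
    "acceptor_stem_3p",
    "tail",               # discriminator base plus CCA(CCA) if present
)


@dataclass
class ArmAnnotation:
    """Cloverleaf decomposition of one gene: half-open sequential
    intervals, one per region in :data:`REGIONS`."""

    sequence: str
    dot_bracket: str
    intervals: dict[str, tuple[int, int]]
    pairs: dict[int, int] = field(repr=False, default_factory=dict)

    def __getitem__(self, region: str) -> tuple[int, int]:
        return self.intervals[region]

    def length(self, region: str) -> int:
        a, b = self.intervals[region]
        return b - a

    @property
    def anticodon_interval(self) -> tuple[int, int]:
        a, b = self.intervals["anticodon_loop"]
        pre = (b - a - 3) // 2
        return (a + pre, a + pre + 3)

    @property
    def anticodon(self) -> str:
        a, b = self.anticodon_interval
        return self.sequence[a:b]

    def validate(self) -> None:
        cursor = 0
        for name in REGIONS:
            a, b = self.intervals[name]
            if a != cursor or b < a:
                raise ValueError("annotation intervals do not tile the sequence")
            cursor = b
        if cursor != len(self.sequence):
            raise ValueError("annotation intervals do not tile the sequence")


def annotate_cloverleaf(sequence: str, dot_bracket: str) -> ArmAnnotation:
    """Decompose a secondary structure into the thirteen cloverleaf
    regions (plus the two short inter-stem linkers and the 3' tail).

    The structure must consist of one outer (acceptor) stem enclosing
    exactly three clean hairpins: the D arm, the anticodon arm and the
    TPsiC arm.  Anything else raises ``ValueError("not a cloverleaf...")``.
    Unpaired trailing bases (discriminator, CCA) are collected in ``tail``.
    """
    sequence = normalize_seq(sequence)
    if len(sequence) != len(dot_bracket):
        raise ValueError("sequence and structure lengths differ")
    pairs = pair_map(dot_bracket)
    if not pairs or dot_bracket[0] != "(":
        raise ValueError("not a cloverleaf: no closing acceptor stem")
    n = len(dot_bracket)

    j0 = pairs[0]
    k = 1
    while 0 + k < j0 - k and pairs.get(k) == j0 - k:
        k += 1
    acc5 = (0, k)
    acc3 = (j0 - k + 1, j0 + 1)
    if any(p in pairs for p in range(j0 + 1, n)):
        raise ValueError("not a cloverleaf: paired bases after the acceptor stem")
    tail = (j0 + 1, n)

    # walk the multiloop interior collecting unpaired runs and hairpins
    interior_end = j0 - k + 1
    cursor = k
    segments: list[tuple[str, object]] = []
    while cursor < interior_end:
        if cursor in pairs:
            j = pairs[cursor]
            s = 1
            while cursor + s < j - s and pairs.get(cursor + s) == j - s:
                s += 1
            loop = (cursor + s, j - s + 1)
            if any(p in pairs for p in range(*loop)):
                raise ValueError("not a cloverleaf: branched or bulged arm")
            if loop[1] - loop[0] < 3:
                raise ValueError("not a cloverleaf: hairpin loop shorter than 3 nt")
            segments.append(("h", ((cursor, cursor + s), loop, (j - s + 1, j + 1))))
            cursor = j + 1
        else:
            a = cursor
            while cursor < interior_end and cursor not in pairs:
                cursor += 1
            segments.append(("u", (a, cursor)))

    hairpins = [seg for kind, seg in segments if kind == "h"]
    if len(hairpins) != 3:
        raise ValueError(
            f"not a cloverleaf: found {len(hairpins)} hairpin arms, expected 3"
        )

    def unpaired_between(i_before: int, i_after: int) -> tuple[int, int]:
        """Unpaired run between hairpin i_before and i_after (or the
        acceptor stem for -1 / 3)."""
        start = acc5[1] if i_before < 0 else hairpins[i_before][2][1]
        end = interior_end if i_after > 2 else hairpins[i_after][0][0]
        for kind, seg in segments:
            if kind == "u" and seg[0] >= start and seg[1] <= end:
                return seg
        return (start, start)

    linker_ad = unpaired_between(-1, 0)
    linker_da = unpaired_between(0, 1)
    vloop = unpaired_between(1, 2)
    after_t = unpaired_between(2, 3)
    if after_t[1] - after_t[0] != 0:
        raise ValueError("not a cloverleaf: unpaired bases between T arm and acceptor stem")

    (d5, dloop, d3) = hairpins[0]
    (a5, aloop, a3) = hairpins[1]
    (t5, tloop, t3) = hairpins[2]

    intervals = {
        "acceptor_stem_5p": acc5,
        "linker_ad": linker_ad,
        "d_stem_5p": d5,
        "d_loop": dloop,
        "d_stem_3p": d3,
        "linker_da": linker_da,
        "anticodon_stem_5p": a5,
        "anticodon_loop": aloop,
        "anticodon_stem_3p": a3,
        "variable_loop": vloop,
        "t_stem_5p": t5,
        "t_loop": tloop,
        "t_stem_3p": t3,
        "acceptor_stem_3p": acc3,
        "tail": tail,
    }
    ann = ArmAnnotation(sequence, dot_bracket, intervals, pairs)
    ann.validate()
    return ann


def _letters(n: int) -> list[str]:
    if n > 26:
        raise ValueError("insertion run longer than 26 bases")
    return list(string.ascii_lowercase[:n])


def _anchor3(length: int, numbers: list[int], overflow: int) -> list[StructuralLabel]:
    """Labels for a region compressed/padded toward its 3' end: the last
    base always takes numbers[-1]; extra 5' bases become insertions on
    ``overflow`` (the canonical number just upstream of the region)."""
    if length <= len(numbers):
        return [_sl(x) for x in numbers[len(numbers) - length:]]
    extra = length - len(numbers)
    return [_sl(overflow, c) for c in _letters(extra)] + [_sl(x) for x in numbers]


def _anchor5(length: int, numbers: list[int]) -> list[StructuralLabel]:
    if length <= len(numbers):
        return [_sl(x) for x in numbers[:length]]
    extra = length - len(numbers)
    return [_sl(x) for x in numbers] + [_sl(numbers[-1], c) for c in _letters(extra)]


def assign_structural_numbering(ann: ArmAnnotation) -> dict[int, StructuralLabel]:
    """Map every sequential index (0-based) of an annotated gene to a
    structural label.

    The anchor is the T arm: its first paired 5' nucleoside is defined as
    position 49.  The variable loop is numbered backwards from 48 (its
    last base is always 48), with insertions 47a, 47b, ... for type II
    expansions.  The anticodon loop is anchored so the anticodon triplet
    is 34-36.  D-loop length variation is absorbed by compressing or
    padding 14..21 toward the loop's 3' end.  The mapping is total and
    injective; labels are non-decreasing along the sequence.
    """
    m: dict[int, StructuralLabel] = {}

    def put(interval: tuple[int, int], labels: list[StructuralLabel]) -> None:
        a, b = interval
        assert len(labels) == b - a
        for pos, lab in zip(range(a, b), labels):
            m[pos] = lab

    def put_paired(interval: tuple[int, int], pair_sum: int) -> None:
        a, b = interval
        for pos in range(a, b):
            partner = ann.pairs[pos]
            m[pos] = _sl(pair_sum - m[partner].number)

    iv = ann.intervals
    if ann.length("acceptor_stem_5p") > 7:
        raise ValueError("acceptor stem longer than 7 bp is unsupported")
    if ann.length("d_stem_5p") > 4:
        raise ValueError("D stem longer than 4 bp is unsupported")
    if ann.length("anticodon_stem_5p") > 5:
        raise ValueError("anticodon stem longer than 5 bp is unsupported")
    if ann.length("t_stem_5p") > 5:
        raise ValueError("T stem longer than 5 bp is unsupported")

    put(iv["acceptor_stem_5p"], _anchor3(ann.length("acceptor_stem_5p"), list(range(1, 8)), 1))
    put(iv["linker_ad"], _anchor5(ann.length("linker_ad"), [8, 9]))
    put(iv["d_stem_5p"], _anchor3(ann.length("d_stem_5p"), [10, 11, 12, 13], 9))
    put(iv["d_loop"], _anchor3(ann.length("d_loop"), list(range(14, 22)), 13))
    put_paired(iv["d_stem_3p"], 35)
    put(iv["linker_da"], _anchor5(ann.length("linker_da"), [26]))
    put(iv["anticodon_stem_5p"], _anchor3(ann.length("anticodon_stem_5p"), list(range(27, 32)), 26))

    la, lb = iv["anticodon_loop"]
    ac_a, ac_b = ann.anticodon_interval
    pre = ac_a - la
    post = lb - ac_b
    labels = (
        _anchor3(pre, [32, 33], 31)
        + [_sl(34), _sl(35), _sl(36)]
        + _anchor5(post, [37, 38])
    )
    put((la, lb), labels)
    put_paired(iv["anticodon_stem_3p"], 70)

    vl = ann.length("variable_loop")
    if vl <= 5:
        put(iv["variable_loop"], _anchor3(vl, list(range(44, 49)), 43))
    else:
        labels = (
            [_sl(x) for x in (44, 45, 46, 47)]
            + [_sl(47, c) for c in _letters(vl - 5)]
            + [_sl(48)]
        )
        put(iv["variable_loop"], labels)

    t5a, t5b = iv["t_stem_5p"]
    put(iv["t_stem_5p"], [_sl(49 + i) for i in range(t5b - t5a)])
    put(iv["t_loop"], _anchor3(ann.length("t_loop"), list(range(54, 61)), 53))
    put_paired(iv["t_stem_3p"], 114)
    put_paired(iv["acceptor_stem_3p"], 73)
    put(iv["tail"], _anchor5(ann.length("tail"), [73, 74, 75, 76]))

    # sanity: total, injective, non-decreasing
    assert len(m) == len(ann.sequence)
    keys = sorted(m)
    labels_sorted = [m[k] for k in keys]
    assert all(labels_sorted[i].sort_key <= labels_sorted[i + 1].sort_key
               for i in range(len(keys) - 1)), "labels not monotone"
    assert len({(l.number, l.insertion) for l in labels_sorted}) == len(labels_sorted), \
        "structural map not injective"
    return m


@dataclass
class TRNAGene:
    """One tRNA gene in mature-tRNA space.

    ``sequence`` excludes the non-templated CCA tail unless
    ``cca_included`` is set (then the last three bases are the tail and
    the companion structure leaves them unpaired).
    """

    gene_id: str
    isotype: str
    isoacceptor: str
    sequence: str
    dot_bracket: str
    structural_map: dict[int, StructuralLabel] = field(repr=False)
    annotation: ArmAnnotation = field(repr=False)
    cca_included: bool = False

    @classmethod
    def from_structure(
        cls,
        gene_id: str,
        isotype: str,
        isoacceptor: str,
        sequence: str,
        dot_bracket: str,
        cca_included: bool = False,
    ) -> "TRNAGene":
        sequence = normalize_seq(sequence)
        ann = annotate_cloverleaf(sequence, dot_bracket)
        smap = assign_structural_numbering(ann)
        return cls(gene_id, isotype, isoacceptor, sequence, dot_bracket, smap, ann, cca_included)

    def __len__(self) -> int:
        return len(self.sequence)

    def label_of(self, seq_index: int) -> StructuralLabel:
        return self.structural_map[seq_index]

    def seq_index_of(self, label: StructuralLabel | int | str) -> int:
        """0-based sequential index of a structural label (KeyError if the
        gene has no base at that label)."""
        label = StructuralLabel.parse(label)
        for i, lab in self.structural_map.items():
            if lab == label:
                return i
        raise KeyError(f"{self.gene_id} has no base at structural position {label}")

    def cytosine_positions(self) -> list[int]:
        return [i for i, b in enumerate(self.sequence) if b == "C"]


def has_cytosine_at(gene: TRNAGene, labels: Iterable[StructuralLabel | int | str]) -> bool:
    """True iff the gene carries a C at any of the queried structural
    positions.  Unknown (out-of-range) labels raise ``ValueError``."""
    wanted = set()
    for lab in labels:
        try:
            wanted.add(StructuralLabel.parse(lab))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"unknown structural label: {lab!r}") from exc
    if not wanted:
        return False
    return any(
        gene.sequence[i] == "C"
        for i, lab in gene.structural_map.items()
        if lab in wanted
    )


def group_genes(
    genes: list[TRNAGene], level: str = "isotype"
) -> dict[str, list[TRNAGene]]:
    """Partition genes by isotype, isoacceptor, or presence of a cytosine
    at structural 48/49 (keys ``C48/49`` and ``no-C48/49``)."""
    groups: dict[str, list[TRNAGene]] = {}
    for gene in genes:
        if level == "isotype":
            key = gene.isotype
        elif level == "isoacceptor":
            key = f"{gene.isotype}-{gene.isoacceptor}"
        elif level == "c4849":
            key = "C48/49" if has_cytosine_at(gene, [48, 49]) else "no-C48/49"
        else:
            raise ValueError(f"unknown grouping level: {level!r}")
        groups.setdefault(key, []).append(gene)
    return groups
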