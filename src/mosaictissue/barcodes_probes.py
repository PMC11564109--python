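"""Combinatorial codebooks, logical barcodes and encoding-probe design.

Two error-tolerant code families are constructed by deterministic greedy
packing:

* a binary **constant-weight codebook** (default length 22, Hamming weight 4,
  minimum pairwise distance 4) for combinatorial FISH, where unassigned
  codewords serve as *blanks* for false-positive estimation.  A distance-4
  code detects two-bit errors and corrects single-bit errors;
* **quaternary logical barcodes** (default length 7, alphabet {0,1,2,3},
  minimum distance 3) for targeted in situ sequencing, likewise correcting
  single-symbol errors.

Probe design searches each transcript with a sliding 30-mer window, excluding
windows by sequence complexity (long homopolymer runs, low nucleotide
diversity), GC content outside 40-65%, arm melting temperatures below a
threshold or differing by more than 8 degC, and simple hairpin self-complement
matches.  The first windows from the 5' end are kept (default 16).  Encoding
probes then pair homology regions with readout sequences drawn round-robin
from the gene's on-bits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp, gc_fraction

__all__ = [
    "Codebook",
    "BarcodeSet",
    "HomologyRegion",
    "ProbeParams",
    "ProbeRecord",
    "build_merfish_codebook",
    "build_exseq_barcodes",
    "decode",
    "find_homology_regions",
    "assemble_probes",
    "write_probes_fasta",
    "hamming",
]

_BASES = "ACGT"


def hamming(a, b) -> int:
    """Hamming distance between two equal-length symbol sequences."""
    a, b = np.asarray(list(a)), np.asarray(list(b))
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    return int((a != b).sum())


def _bits_to_str(mask: int, length: int) -> str:
    return format(mask, f"0{length}b")


@dataclass
class Codebook:
    """Constant-weight binary codebook with gene and blank codewords."""

    length: int
    weight: int
    min_distance: int
    gene_codewords: dict[str, str]  # gene -> bit-string, MSB first
    blank_codewords: list[str]
    readout_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.readout_ids:
            self.readout_ids = [f"R{i + 1:02d}" for i in range(self.length)]
        for word in self.all_codewords():
            if len(word) != self.length or word.count("1") != self.weight:
                raise ValueError(f"codeword {word} violates length/weight invariants")
        if set(self.gene_codewords.values()) & set(self.blank_codewords):
            raise ValueError("gene and blank codewords must be disjoint")

    def all_codewords(self) -> list[str]:
        return list(self.gene_codewords.values()) + list(self.blank_codewords)

    def labels(self) -> dict[str, str]:
        out = {w: g for g, w in self.gene_codewords.items()}
        for i, w in enumerate(self.blank_codewords):
            out[w] = f"blank{i:03d}"
        return out

    def on_bits(self, gene: str) -> list[int]:
        word = self.gene_codewords[gene]
        return [i for i, b in enumerate(word) if b == "1"]


@dataclass
class BarcodeSet:
    """Quaternary logical barcodes with a guaranteed minimum distance."""

    length: int
    alphabet_size: int
    min_distance: int
    gene_barcodes: dict[str, tuple[int, ...]]

    def __post_init__(self) -> None:
        seen = set()
        for gene, bc in self.gene_barcodes.items():
            if len(bc) != self.length or any(not 0 <= s < self.alphabet_size for s in bc):
                raise ValueError(f"barcode for {gene} violates length/alphabet invariants")
            if bc in seen:
                raise ValueError("barcodes must be distinct")
            seen.add(bc)


#: Internal seed for the packing search.  The packing is deterministic and
#: independent of the caller's assignment seed.
_SEARCH_SEED = 2022


def _greedy_pass(cands: np.ndarray, order: np.ndarray, min_distance: int, seed_set: np.ndarray):
    acc = seed_set.copy() if len(seed_set) else np.empty((0, cands.shape[1]), dtype=np.int8)
    for i in order:
        c = cands[i]
        if acc.shape[0] == 0 or (acc != c).sum(axis=1).min() >= min_distance:
            acc = np.vstack([acc, c[None]])
    return acc


def _pack_symbols(
    cands_key: tuple, min_distance: int, target: int, n_restarts: int = 3, budget: int = 40
) -> np.ndarray:
    """Maximize a code by seeded greedy restarts plus remove-and-readd search.

    Greedy passes over random candidate orders are followed by a local
    augmentation loop (drop 1-3 accepted words, re-add greedily); the best set
    found is returned.  The search stops early once ``target`` words are
    packed.  Deterministic: all randomness comes from :data:`_SEARCH_SEED`.
    """
    cands = np.array(cands_key, dtype=np.int8)
    rng = np.random.default_rng(_SEARCH_SEED)
    n = len(cands)
    best = np.empty((0, cands.shape[1]), dtype=np.int8)
    for _ in range(n_restarts):
        acc = _greedy_pass(cands, rng.permutation(n), min_distance, best[:0])
        if len(acc) > len(best):
            best = acc
        if len(best) >= target:
            return best
    current = best.copy()
    for _ in range(budget):
        trial = current.copy()
        k = int(rng.integers(1, 4))
        keep = np.ones(len(trial), dtype=bool)
        keep[rng.choice(len(trial), size=k, replace=False)] = False
        trial = _greedy_pass(cands, rng.permutation(n), min_distance, trial[keep])
        if len(trial) >= len(current):
            current = trial
        if len(current) > len(best):
            best = current.copy()
        if len(best) >= target:
            break
    return best


_PACK_CACHE: dict[tuple, np.ndarray] = {}


def _pack_cached(cands_key: tuple, min_distance: int, target: int) -> np.ndarray:
    key = (hash(cands_key), min_distance, target)
    if key not in _PACK_CACHE:
        _PACK_CACHE[key] = _pack_symbols(cands_key, min_distance, target)
    return _PACK_CACHE[key]


def build_merfish_codebook(
    n_genes: int,
    n_blanks_requested: int = 94,
    seed: int = 0,
    gene_names: list[str] | None = None,
    length: int = 22,
    weight: int = 4,
    min_distance: int = 4,
) -> Codebook:
    """Build a constant-weight codebook by seeded greedy packing.

    All ``C(length, weight)`` constant-weight words are candidates; a word is
    accepted iff it is at Hamming distance >= ``min_distance`` from every
    previously accepted word.  A deterministic restart-and-augment search (see
    :func:`_pack_symbols`) maximizes the packing; the accepted words are then
    shuffled by ``seed``, the first ``n_genes`` assigned to genes and the
    remainder (up to ``n_blanks_requested``) reserved as blanks.

    Greedy packing does not promise the combinatorial optimum (385 for the
    default 22/4/4 parameters); raises if the achieved code is smaller than
    ``n_genes`` plus one blank.
    """
    if gene_names is None:
        gene_names = [f"gene{i:04d}" for i in range(n_genes)]
    if len(gene_names) != n_genes:
        raise ValueError("gene_names length must equal n_genes")
    cands_key = tuple(
        tuple(1 if i in comb else 0 for i in range(length))
        for comb in combinations(range(length), weight)
    )
    words = _pack_cached(cands_key, min_distance, n_genes + n_blanks_requested)
    if len(words) < n_genes + 1:
        raise ValueError(
            f"infeasible request: packing achieved only {len(words)} codewords "
            f"(< {n_genes} genes requested plus one blank)"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(words))
    shuffled = ["".join(str(int(b)) for b in words[i]) for i in order]
    gene_words = shuffled[:n_genes]
    blanks = shuffled[n_genes : n_genes + n_blanks_requested]
    return Codebook(
        length=length,
        weight=weight,
        min_distance=min_distance,
        gene_codewords=dict(zip(gene_names, gene_words)),
        blank_codewords=blanks,
    )


def build_exseq_barcodes(
    n_genes: int,
    seed: int = 0,
    gene_names: list[str] | None = None,
    length: int = 7,
    alphabet_size: int = 4,
    min_distance: int = 3,
) -> BarcodeSet:
    """Greedy packing of quaternary barcodes with pairwise distance >= 3.

    Candidates are all ``alphabet_size ** length`` words; acceptance and the
    deterministic restart-and-augment search mirror
    :func:`build_merfish_codebook`.  Accepted barcodes are shuffled by
    ``seed`` and assigned to genes; deterministic given the seed.
    """
    n_words = alphabet_size**length
    digits = np.empty((n_words, length), dtype=np.int8)
    vals = np.arange(n_words)
    for pos in range(length - 1, -1, -1):
        digits[:, pos] = vals % alphabet_size
        vals //= alphabet_size
    accepted = _pack_cached(tuple(map(tuple, digits.tolist())), min_distance, n_genes)
    n_acc = len(accepted)
    if n_acc < n_genes:
        raise ValueError(
            f"infeasible request: greedy packing achieved only {n_acc} barcodes"
        )
    if gene_names is None:
        gene_names = [f"gene{i:04d}" for i in range(n_genes)]
    if len(gene_names) != n_genes:
        raise ValueError("gene_names length must equal n_genes")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_acc)[:n_genes]
    barcodes = {g: tuple(int(s) for s in accepted[i]) for g, i in zip(gene_names, order)}
    return BarcodeSet(
        length=length,
        alphabet_size=alphabet_size,
        min_distance=min_distance,
        gene_barcodes=barcodes,
    )


def decode(word, code: Codebook | BarcodeSet) -> str | None:
    """Decode a measured word: exact match, unique correction, or reject.

    A word matching a codeword exactly returns that codeword's label; a word
    with a *unique* codeword within radius ``floor((d - 1) / 2)`` is corrected
    to it; anything else returns ``None`` (reject).
    """
    if isinstance(code, Codebook):
        word = "".join(str(int(b)) for b in word) if not isinstance(word, str) else word
        if len(word) != code.length:
            raise ValueError("word length does not match code length")
        cache = getattr(code, "_decode_cache", None)
        if cache is None:
            labels = code.labels()
            cache = (
                list(labels.values()),
                np.array([[int(b) for b in w] for w in labels], dtype=np.int8),
            )
            object.__setattr__(code, "_decode_cache", cache)
        word_arr = np.frombuffer(word.encode(), dtype=np.uint8).astype(np.int8) - ord("0")
    else:
        word = tuple(int(s) for s in word)
        if len(word) != code.length:
            raise ValueError("word length does not match code length")
        cache = getattr(code, "_decode_cache", None)
        if cache is None:
            cache = (
                list(code.gene_barcodes.keys()),
                np.array(list(code.gene_barcodes.values()), dtype=np.int8),
            )
            object.__setattr__(code, "_decode_cache", cache)
        word_arr = np.array(word, dtype=np.int8)
    names, matrix = cache
    radius = (code.min_distance - 1) // 2
    dists = (matrix != word_arr).sum(axis=1)
    best = int(dists.min())
    matches = np.flatnonzero(dists == best)
    if best == 0 or (best <= radius and len(matches) == 1):
        return names[int(matches[0])]
    return None


# ---------------------------------------------------------------------------
# probe design


@dataclass
class ProbeParams:
    """Tunables for the sliding-window homology search.

    Melting temperatures use nearest-neighbor thermodynamics (SantaLucia 2004
    parameter table via Biopython's ``Tm_NN``); the per-arm threshold defaults
    to 37 degC and is configurable per gene.
    """

    window: int = 30
    arm_split: int = 15
    max_homopolymer_run: int = 5  # exclude runs strictly longer than this
    min_unique_bases: int = 4  # exclude windows with fewer distinct bases
    gc_min: float = 0.40
    gc_max: float = 0.65
    tm_threshold: float = 37.0
    max_tm_diff: float = 8.0
    max_regions: int = 16
    hairpin_min_len: int = 6
    screen_hairpins: bool = True
    cross_homology_screen: object | None = None  # pluggable, off by default


@dataclass
class HomologyRegion:
    transcript_id: str
    start: int  # 0-based; end = start + len(sequence), half-open
    sequence: str
    arm_split: int
    tm_left: float
    tm_right: float
    gc: float

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)


def _max_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _has_hairpin(seq: str, min_len: int) -> bool:
    """Reverse-complement self-match of >= ``min_len`` bases within the window."""
    rc = str(Seq(seq).reverse_complement())
    for i in range(len(seq) - min_len + 1):
        if seq[i : i + min_len] in rc:
            return True
    return False


def window_passes(seq: str, params: ProbeParams) -> bool:
    """Apply all per-window exclusion rules to one candidate 30-mer."""
    seq = seq.upper()
    if any(b not in _BASES for b in seq):
        return False
    if _max_run(seq) > params.max_homopolymer_run:
        return False
    if len(set(seq)) < params.min_unique_bases:
        return False
    gc = gc_fraction(seq)
    if not params.gc_min <= gc <= params.gc_max:
        return False
    left, right = seq[: params.arm_split], seq[params.arm_split :]
    tm_left = MeltingTemp.Tm_NN(left)
    tm_right = MeltingTemp.Tm_NN(right)
    if tm_left < params.tm_threshold or tm_right < params.tm_threshold:
        return False
    if abs(tm_left - tm_right) > params.max_tm_diff:
        return False
    if params.screen_hairpins and _has_hairpin(seq, params.hairpin_min_len):
        return False
    return True


def find_homology_regions(
    transcript, params: ProbeParams | None = None, transcript_id: str | None = None
) -> list[HomologyRegion]:
    """Sliding-window search for probe homology regions along a transcript.

    Accepts a ``Bio.SeqRecord``, ``Seq`` or plain string.  Surviving windows
    are collected greedily from the 5' end without overlap, up to
    ``params.max_regions`` (all if fewer).  An optional cross-transcript
    homology screen (``params.cross_homology_screen``, a callable taking the
    window sequence and returning True to exclude) is applied last and is off
    by default.
    """
    params = params or ProbeParams()
    if hasattr(transcript, "seq"):
        seq = str(transcript.seq).upper()
        transcript_id = transcript_id or transcript.id
    else:
        seq = str(transcript).upper()
        transcript_id = transcript_id or "transcript"
    if len(seq) < params.window:
        raise ValueError(
            f"transcript {transcript_id} shorter than the {params.window}-nt window"
        )
    regions: list[HomologyRegion] = []
    pos = 0
    while pos <= len(seq) - params.window and len(regions) < params.max_regions:
        window = seq[pos : pos + params.window]
        ok = window_passes(window, params)
        if ok and params.cross_homology_screen is not None:
            ok = not params.cross_homology_screen(window)
        if ok:
            left, right = window[: params.arm_split], window[params.arm_split :]
            regions.append(
                HomologyRegion(
                    transcript_id=transcript_id,
                    start=pos,
                    sequence=window,
                    arm_split=params.arm_split,
                    tm_left=float(MeltingTemp.Tm_NN(left)),
                    tm_right=float(MeltingTemp.Tm_NN(right)),
                    gc=float(gc_fraction(window)),
                )
            )
            pos += params.window  # non-overlapping windows
        else:
            pos += 1
    return regions


@dataclass
class ProbeRecord:
    name: str
    gene: str
    target_sequence: str
    readouts: tuple[str, ...]
    sequence: str


def _readout_sequences(readout_ids: list[str], seed: int = 1234, length: int = 20) -> dict:
    """Deterministic placeholder 20-mer readout sequences, one per bit."""
    rng = np.random.default_rng(seed)
    return {
        rid: "".join(rng.choice(list(_BASES), size=length)) for rid in sorted(readout_ids)
    }


_PRIMER_5 = "CGCGGTTCAGCAGGAATGCC"
_PRIMER_3 = "GGTACTCGCAGTAGTCGCGT"


def assemble_probes(
    regions: list[HomologyRegion],
    gene: str,
    codebook: Codebook | None = None,
    probes_per_gene: int = 60,
    readouts_per_probe: int = 3,
    sequential_readout: str | None = None,
) -> list[ProbeRecord]:
    """Assemble encoding probes from homology regions and code assignments.

    Combinatorial genes get up to ``probes_per_gene`` probes (default 60),
    each carrying ``readouts_per_probe`` readout sequences (default 3) chosen
    round-robin from the gene's on-bits so that usage across on-bits is
    balanced within one, plus constant primer flanks.  Sequential genes
    (``sequential_readout`` given) get one unique readout and no primers;
    callers pass ``probes_per_gene=48`` for the standard sequential design.

    If fewer regions than probes are available, all regions are used and a
    warning is emitted.
    """
    if not regions:
        raise ValueError(f"no homology regions available for {gene}")
    if sequential_readout is None:
        if codebook is None:
            raise ValueError("combinatorial probes require a codebook")
        on_bits = codebook.on_bits(gene)
        if len(on_bits) < readouts_per_probe:
            raise ValueError(
                f"{gene}: codeword has {len(on_bits)} on-bits < {readouts_per_probe}"
            )
        readout_ids = [codebook.readout_ids[b] for b in on_bits]
    else:
        readout_ids = [sequential_readout]
        readouts_per_probe = 1

    n_probes = min(probes_per_gene, len(regions))
    if n_probes < probes_per_gene:
        warnings.warn(
            f"{gene}: only {len(regions)} homology regions for {probes_per_gene} "
            "requested probes; emitting all available"
        )
    seqs = _readout_sequences(readout_ids)
    probes = []
    for j in range(n_probes):
        region = regions[j]
        if sequential_readout is None:
            # drop one on-bit per probe in rotation: each readout is used in
            # readouts_per_probe of every len(readout_ids) probes
            drop = j % len(readout_ids)
            chosen = tuple(r for i, r in enumerate(readout_ids) if i != drop)[
                :readouts_per_probe
            ]
            flank5, flank3 = _PRIMER_5, _PRIMER_3
        else:
            chosen = (sequential_readout,)
            flank5 = flank3 = ""
        target = str(Seq(region.sequence).reverse_complement())
        body = seqs[chosen[0]] + target + "".join(seqs[r] for r in chosen[1:])
        probes.append(
            ProbeRecord(
                name=f"{gene}_probe{j:03d}",
                gene=gene,
                target_sequence=region.sequence,
                readouts=chosen,
                sequence=flank5 + body + flank3,
            )
        )
    return probes


def write_probes_fasta(probes: list[ProbeRecord], path) -> None:
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(
            Seq(p.sequence), id=p.name, description=f"gene={p.gene} readouts={','.join(p.readouts)}"
        )
        for p in probes
    ]
    seqio_write(records, str(path), "fasta")
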