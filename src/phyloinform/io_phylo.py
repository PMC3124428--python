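"""Reading and validation of alignments, ultrametric trees, and rate files.

Alignments are accepted in FASTA, Phylip (strict/relaxed, sequential or
interleaved) and NEXUS; trees in Newick or NEXUS (translate tables are
resolved).  NEXUS ``charset`` statements become named partitions, including
the range ``a-b`` and codon-step ``a-b\\3`` syntaxes.  Per-site rate vectors
travel in a simple TSV (one row per site, ``NA`` marking faulty sites) that
round-trips exactly.

All site coordinates on every file interface are 1-based inclusive,
matching the NEXUS convention.
"""

from __future__ import annotations

import io
import math
import re
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio import SeqIO, AlignIO
from Bio.Nexus import Nexus

__all__ = [
    "Alignment",
    "UltrametricTree",
    "SiteRateVector",
    "FormatError",
    "ValidationError",
    "read_alignment",
    "read_tree",
    "read_rate_vectors",
    "write_rate_vectors",
    "write_profile_table",
    "write_ranking",
    "reconcile",
    "DNA_STATES",
    "PROTEIN_STATES",
    "state_set",
]


class FormatError(ValueError):
    """A file could not be parsed in any accepted format."""


class ValidationError(ValueError):
    """Parsed content violates an invariant (lengths, labels, ultrametricity...)."""


# ---------------------------------------------------------------------------
# alphabets

DNA_STATES = "ACGT"
PROTEIN_STATES = "ARNDCQEGHILKMFPSTWYV"

# IUPAC nucleotide ambiguity codes -> possible states; fully-missing symbols
# ("?", "-", "N", and "X") map to the complete state set.
_DNA_AMBIG = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "X": "ACGT", "-": "ACGT", "?": "ACGT", ".": "ACGT",
}
_PROTEIN_AMBIG = {aa: aa for aa in PROTEIN_STATES}
_PROTEIN_AMBIG.update({
    "B": "DN", "Z": "EQ", "J": "IL",
    "X": PROTEIN_STATES, "-": PROTEIN_STATES, "?": PROTEIN_STATES,
    "*": PROTEIN_STATES, ".": PROTEIN_STATES,
})

_MISSING = {"-", "?", "N", "X", ".", "*"}


def state_set(symbol: str, alphabet: str) -> tuple[int, ...]:
    """Indices of the states compatible with an observed symbol.

    A fully-missing symbol returns the whole state set (its conditional
    likelihood is a vector of ones).  Unknown symbols raise.
    """
    symbol = symbol.upper()
    table = _DNA_AMBIG if alphabet == "DNA" else _PROTEIN_AMBIG
    states = DNA_STATES if alphabet == "DNA" else PROTEIN_STATES
    try:
        chars = table[symbol]
    except KeyError:
        raise ValidationError(f"symbol {symbol!r} is not valid for alphabet {alphabet}")
    return tuple(states.index(c) for c in chars)


def is_missing(symbol: str, alphabet: str) -> bool:
    """True if the symbol carries no state information."""
    s = symbol.upper()
    if alphabet == "DNA":
        return s in {"-", "?", "N", "X", "."}
    return s in {"-", "?", "X", "*", "."}


# ---------------------------------------------------------------------------
# domain types


@dataclass
class Alignment:
    """An aligned locus: equal-length sequence rows over DNA or protein.

    ``partitions`` maps partition names to sorted lists of 1-based column
    indices (NEXUS charsets).  Overlapping partitions are allowed with a
    warning; out-of-range columns are an error.
    """

    locus_name: str
    taxa: list[str]
    sequences: list[str]
    alphabet: str  # "DNA" | "PROTEIN"
    partitions: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.taxa:
            raise ValidationError(f"alignment {self.locus_name!r} has no sequences")
        if len(self.taxa) != len(self.sequences):
            raise ValidationError("taxa and sequence counts differ")
        seen = set()
        for t in self.taxa:
            if not t:
                raise ValidationError("empty taxon label")
            if t in seen:
                raise ValidationError(f"duplicate taxon label {t!r}")
            seen.add(t)
        L = len(self.sequences[0])
        if L < 1:
            raise ValidationError(f"alignment {self.locus_name!r} has zero columns")
        for t, s in zip(self.taxa, self.sequences):
            if len(s) != L:
                raise ValidationError(
                    f"alignment malformed: row for taxon {t!r} has length "
                    f"{len(s)}, expected {L}"
                )
        if self.alphabet not in ("DNA", "PROTEIN"):
            raise ValidationError(f"unknown alphabet {self.alphabet!r}")
        table = _DNA_AMBIG if self.alphabet == "DNA" else _PROTEIN_AMBIG
        for t, s in zip(self.taxa, self.sequences):
            bad = set(s.upper()) - set(table)
            if bad:
                raise ValidationError(
                    f"taxon {t!r} contains symbols {sorted(bad)} invalid for "
                    f"{self.alphabet}"
                )
        cover: dict[int, str] = {}
        for name, cols in self.partitions.items():
            for c in cols:
                if not (1 <= c <= L):
                    raise ValidationError(
                        f"partition {name!r} column {c} outside [1, {L}]"
                    )
                if c in cover and cover[c] != name:
                    warnings.warn(
                        f"partitions {cover[c]!r} and {name!r} overlap at column {c}"
                    )
                cover.setdefault(c, name)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def column(self, i: int) -> dict[str, str]:
        """Observed symbols at 1-based column i, keyed by taxon."""
        return {t: s[i - 1].upper() for t, s in zip(self.taxa, self.sequences)}

    def subset(self, name: str, columns: list[int]) -> "Alignment":
        """A pseudo-locus holding only the given 1-based columns."""
        idx = [c - 1 for c in columns]
        return Alignment(
            locus_name=name,
            taxa=list(self.taxa),
            sequences=["".join(s[i] for i in idx) for s in self.sequences],
            alphabet=self.alphabet,
        )


@dataclass
class UltrametricTree:
    """A rooted tree whose tips are all equidistant from the root.

    Branch lengths are in time units or unspecified molecular-evolutionary
    units; ``depth`` is the shared root-to-tip distance and fixes the time
    axis for profiles (t=0 at the tips).
    """

    tree: dendropy.Tree
    depth: float

    @property
    def taxa(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def scaled(self, c: float) -> "UltrametricTree":
        """A copy with every branch length multiplied by c > 0."""
        if c <= 0:
            raise ValueError("scale factor must be positive")
        t2 = self.tree.clone(depth=1)
        for e in t2.edges():
            if e.length is not None:
                e.length = e.length * c
        return UltrametricTree(tree=t2, depth=self.depth * c)

    def pruned_to(self, taxa: set[str]) -> "UltrametricTree":
        """A copy retaining only the given tip labels (depth recomputed)."""
        t2 = self.tree.clone(depth=1)
        keep = [t for t in t2.taxon_namespace if t.label in taxa]
        t2.retain_taxa(keep)
        return _finalize_tree(t2, tolerance=math.inf)


def _finalize_tree(tree: dendropy.Tree, tolerance: float = 1e-4) -> UltrametricTree:
    """Validate branch lengths and ultrametricity; compute depth."""
    leaves = tree.leaf_nodes()
    if len(leaves) < 2:
        raise ValidationError("tree must have at least 2 tips")
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            label = node.taxon.label if node.taxon else "(internal)"
            raise ValidationError(f"missing branch length on edge above {label}")
        if node.edge.length < 0:
            raise ValidationError("negative branch length")
    depths = {}
    for node in tree.preorder_node_iter():
        parent_d = depths.get(node.parent_node, 0.0)
        depths[node] = parent_d + (node.edge.length or 0.0)
    tip_depths = np.array([depths[leaf] for leaf in leaves])
    depth = float(tip_depths.max())
    if depth <= 0:
        raise ValidationError("tree depth must be positive")
    dev = float(np.abs(tip_depths - depth).max())
    if dev > tolerance * depth:
        raise ValidationError(
            f"tree is not ultrametric: max tip-depth deviation {dev:.6g} "
            f"exceeds {tolerance:g} x depth ({depth:.6g})"
        )
    return UltrametricTree(tree=tree, depth=depth)


@dataclass
class SiteRateVector:
    """Per-site rate estimates for one locus, with a faulty-site mask.

    Faulty sites (no rate could be estimated) carry NaN in ``rates`` and
    True in ``faulty``; they are written as ``NA`` and excluded from
    profiles.  ``n_estimated + n_faulty`` equals the locus length.
    """

    locus_name: str
    rates: np.ndarray
    faulty: np.ndarray
    model_tag: str = ""

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.faulty = np.asarray(self.faulty, dtype=bool)
        if self.rates.shape != self.faulty.shape or self.rates.ndim != 1:
            raise ValidationError("rates and faulty mask must be equal-length 1-D")
        ok = self.rates[~self.faulty]
        if ok.size and (np.any(ok < 0) or np.any(~np.isfinite(ok))):
            raise ValidationError("non-faulty rates must be finite and >= 0")

    @property
    def length(self) -> int:
        return self.rates.size

    @property
    def n_estimated(self) -> int:
        return int((~self.faulty).sum())

    @property
    def n_faulty(self) -> int:
        return int(self.faulty.sum())


# ---------------------------------------------------------------------------
# alignment reading


def _sniff_format(text: str) -> str:
    for line in text.splitlines():
        s = line.strip()
        if not s:
            continue
        if s.startswith(">"):
            return "fasta"
        if s.upper().startswith("#NEXUS"):
            return "nexus"
        parts = s.split()
        if len(parts) >= 2:
            try:
                int(parts[0]), int(parts[1])
                return "phylip"
            except ValueError:
                pass
        break
    raise FormatError("could not determine alignment format (line 1)")


def detect_alphabet(sequences: list[str]) -> str:
    """DNA if >= 80% of non-gap symbols are in {A,C,G,T,U,N}, else PROTEIN."""
    chars = "".join(sequences).upper().replace("-", "").replace("?", "").replace(".", "")
    if not chars:
        return "DNA"
    dna = sum(chars.count(c) for c in "ACGTUN")
    return "DNA" if dna / len(chars) >= 0.8 else "PROTEIN"


_CHARSET_RE = re.compile(
    r"^\s*charset\s+(\S+)\s*=\s*([^;]+);", re.IGNORECASE | re.MULTILINE
)


def parse_charset_spec(spec: str, length: int) -> list[int]:
    """Expand a NEXUS charset position list into sorted 1-based columns.

    Grammar per token: ``a`` (single column), ``a-b`` (inclusive range),
    ``a-b\\k`` (every k-th column from a through b), with ``.`` standing
    for the last column.
    """
    cols: set[int] = set()
    for token in spec.split():
        m = re.fullmatch(r"(\d+|\.)(?:\s*-\s*(\d+|\.)(?:\\(\d+))?)?", token)
        if not m:
            raise FormatError(f"bad charset token {token!r}")
        a = length if m.group(1) == "." else int(m.group(1))
        if m.group(2) is None:
            cols.add(a)
            continue
        b = length if m.group(2) == "." else int(m.group(2))
        step = int(m.group(3)) if m.group(3) else 1
        if step < 1 or b < a:
            raise FormatError(f"bad charset range {token!r}")
        cols.update(range(a, b + 1, step))
    return sorted(cols)


def _parse_nexus_alignment(text: str, locus_name: str) -> tuple[list[str], list[str], dict[str, list[int]]]:
    try:
        nex = Nexus.Nexus(io.StringIO(text))
    except Exception as exc:  # Bio.Nexus raises NexusError subclasses
        raise FormatError(f"NEXUS parse failure: {exc}") from exc
    if not nex.matrix:
        raise FormatError("NEXUS file contains no character matrix")
    taxa = [str(t) for t in nex.unaltered_taxlabels or nex.taxlabels]
    seqs = [str(nex.matrix[t]) for t in taxa]
    length = max(len(s) for s in seqs)
    partitions: dict[str, list[int]] = {}
    for name, spec in _CHARSET_RE.findall(text):
        partitions[name] = parse_charset_spec(spec, length)
    return taxa, seqs, partitions


def _parse_fasta(text: str) -> tuple[list[str], list[str]]:
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not records:
        raise FormatError("no FASTA records found")
    return [r.id for r in records], [str(r.seq) for r in records]


def _parse_phylip(text: str) -> tuple[list[str], list[str]]:
    last_exc: Exception | None = None
    for dialect in ("phylip-relaxed", "phylip", "phylip-sequential"):
        try:
            aln = AlignIO.read(io.StringIO(text), dialect)
            return [r.id for r in aln], [str(r.seq) for r in aln]
        except Exception as exc:
            last_exc = exc
    raise FormatError(f"Phylip parse failure: {last_exc}")


def read_alignment(
    path,
    format_hint: str | None = None,
    locus_name: str | None = None,
    alphabet: str | None = None,
) -> Alignment:
    """Read and validate one locus alignment (FASTA / Phylip / NEXUS).

    The format is sniffed from the first non-blank line unless
    ``format_hint`` is given.  The alphabet is auto-detected unless
    overridden.  NEXUS charsets populate ``partitions``.
    """
    path = str(path)
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    fmt = format_hint or _sniff_format(text)
    if fmt not in ("fasta", "phylip", "nexus"):
        raise FormatError(f"unknown format hint {fmt!r}")
    partitions: dict[str, list[int]] = {}
    if fmt == "fasta":
        taxa, seqs = _parse_fasta(text)
    elif fmt == "phylip":
        taxa, seqs = _parse_phylip(text)
    else:
        taxa, seqs, partitions = _parse_nexus_alignment(text, path)
    # row-length validation before Alignment so the offending taxon is named
    L = len(seqs[0])
    for t, s in zip(taxa, seqs):
        if len(s) != L:
            raise ValidationError(
                f"alignment malformed in {path}: taxon {t!r} has {len(s)} "
                f"columns, expected {L}"
            )
    if locus_name is None:
        locus_name = re.sub(r"\.[^.]*$", "", path.rsplit("/", 1)[-1])
    return Alignment(
        locus_name=locus_name,
        taxa=taxa,
        sequences=[s.upper().replace("U", "T") if (alphabet or detect_alphabet(seqs)) == "DNA" else s.upper() for s in seqs],
        alphabet=alphabet or detect_alphabet(seqs),
        partitions=partitions,
    )


# ---------------------------------------------------------------------------
# tree reading


def read_tree(path, tolerance: float = 1e-4) -> UltrametricTree:
    """Read an ultrametric tree from Newick or a NEXUS TREES block.

    If the file holds several trees the first is used (with a warning).
    Tip depths must agree with the maximum root-to-tip distance to within
    ``tolerance`` (relative); trees with a basal trifurcation are accepted
    and treated as rooted at that node.
    """
    path = str(path)
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    schema = "nexus" if text.lstrip().upper().startswith("#NEXUS") else "newick"
    try:
        trees = dendropy.TreeList.get(
            data=text, schema=schema, preserve_underscores=True,
            rooting="force-rooted",
        )
    except Exception as exc:
        raise FormatError(f"tree parse failure in {path}: {exc}") from exc
    if len(trees) == 0:
        raise FormatError(f"no trees found in {path}")
    if len(trees) > 1:
        warnings.warn(f"{path} contains {len(trees)} trees; using the first")
    return _finalize_tree(trees[0], tolerance=tolerance)


def reconcile(alignment: Alignment, tree: UltrametricTree) -> UltrametricTree:
    """Match the tree to the alignment's taxon set.

    Tree tips absent from the alignment are pruned (with a warning);
    alignment taxa absent from the tree are a hard error.
    """
    aln_taxa = set(alignment.taxa)
    tree_taxa = set(tree.taxa)
    missing = aln_taxa - tree_taxa
    if missing:
        raise ValidationError(
            f"alignment {alignment.locus_name!r} taxa missing from tree: "
            f"{sorted(missing)}"
        )
    extra = tree_taxa - aln_taxa
    if extra:
        warnings.warn(
            f"pruning {len(extra)} tree tip(s) absent from alignment "
            f"{alignment.locus_name!r}: {sorted(extra)}"
        )
        return tree.pruned_to(aln_taxa)
    return tree


# ---------------------------------------------------------------------------
# rate-vector TSV

_RATE_HEADER = "locus\tsite\trate\tmodel"


def write_rate_vectors(vectors: list[SiteRateVector], path) -> None:
    """Write the canonical site-rate TSV (one row per site, NA = faulty)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_RATE_HEADER + "\n")
        for v in vectors:
            for i in range(v.length):
                rate = "NA" if v.faulty[i] else repr(float(v.rates[i]))
                fh.write(f"{v.locus_name}\t{i + 1}\t{rate}\t{v.model_tag}\n")


def read_rate_vectors(path) -> list[SiteRateVector]:
    """Read a site-rate TSV back into one SiteRateVector per locus block."""
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        warnings.warn(f"rate file {path} is empty")
        return []
    if lines[0].strip().lower() != _RATE_HEADER:
        raise FormatError(
            f"rate file {path} line 1: expected header {_RATE_HEADER!r}"
        )
    blocks: dict[str, dict[int, tuple[float, str]]] = {}
    order: list[str] = []
    for ln_no, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != 4:
            raise FormatError(f"rate file {path} line {ln_no}: expected 4 columns")
        locus, site_s, rate_s, model = parts
        try:
            site = int(site_s)
        except ValueError:
            raise FormatError(f"rate file {path} line {ln_no}: bad site {site_s!r}")
        if rate_s == "NA":
            rate = math.nan
        else:
            try:
                rate = float(rate_s)
            except ValueError:
                raise FormatError(
                    f"rate file {path} line {ln_no}: bad rate {rate_s!r}"
                )
            if rate < 0:
                raise ValidationError(
                    f"rate file {path} line {ln_no}: negative rate {rate}"
                )
        if locus not in blocks:
            blocks[locus] = {}
            order.append(locus)
        if site in blocks[locus]:
            raise ValidationError(
                f"rate file {path} line {ln_no}: duplicate site {site} for "
                f"locus {locus!r}"
            )
        blocks[locus][site] = (rate, model)
    vectors = []
    for locus in order:
        sites = blocks[locus]
        L = max(sites)
        if sorted(sites) != list(range(1, L + 1)):
            raise ValidationError(
                f"rate file {path}: locus {locus!r} sites are not contiguous 1..{L}"
            )
        rates = np.array([sites[i][0] for i in range(1, L + 1)])
        faulty = np.isnan(rates)
        model = next((sites[i][1] for i in range(1, L + 1)), "")
        vectors.append(
            SiteRateVector(locus_name=locus, rates=rates, faulty=faulty,
                           model_tag=model)
        )
    return vectors


# ---------------------------------------------------------------------------
# spreadsheet writers


def write_profile_table(profile, path) -> None:
    """CSV of profile points: time, then <locus>_net and <locus>_persite."""
    loci = list(profile.loci)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        header = ["time"]
        for name in loci:
            header += [f"{name}_net", f"{name}_persite"]
        fh.write(",".join(header) + "\n")
        for k, t in enumerate(profile.grid):
            row = [f"{t:.10g}"]
            for name in loci:
                net, per = profile.curves[name]
                row += [f"{net[k]:.10g}", f"{per[k]:.10g}"]
            fh.write(",".join(row) + "\n")


def write_ranking(ranking, path) -> None:
    """CSV of one epoch's ranking: rank, locus, epoch bounds, both integrals."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("rank,locus,t_start,t_end,integral_net,integral_persite\n")
        for e in ranking.entries:
            fh.write(
                f"{e.rank},{e.locus},{ranking.epoch.t_start:.10g},"
                f"{ranking.epoch.t_end:.10g},{e.integral_net:.10g},"
                f"{e.integral_per_site:.10g}\n"
            )
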