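"""Information-theory models of transcription-factor operator sites.

An aligned set of fixed-width binding sites (ARG boxes) is turned into a
per-position, per-base weight matrix in bits::

    riw(b, l) = log2( f(b, l) / p(b) ) - e(n)

where ``f(b, l)`` is the (optionally pseudocounted) observed frequency of
base ``b`` at position ``l``, ``p(b)`` the background probability and
``e(n)`` an optional small-sample correction.  With the uniform background
this is the familiar ``2 + log2 f`` form with a 2-bit per-position ceiling.
The individual information ``R_i`` of a window is the sum of its matrix
entries; the mean ``R_i`` over the training alignment is ``R_sequence``,
the total information content of the site set.

Operator sites of hexameric repressors such as ArgR are imperfect
palindromes, so a model may be *symmetrized*: the reverse complements of
all training sites are appended before counting, which makes the matrix
exactly reverse-complement symmetric.  Tandem operators (two boxes joined
by a short neutral spacer) are modelled by duplicating the box matrix
around spacer positions that contribute exactly zero bits.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SiteSet",
    "InformationModel",
    "TandemModel",
    "ScanHit",
    "build_site_matrix",
    "score_site",
    "make_tandem",
    "scan",
    "rsequence",
    "per_position_information",
    "reverse_complement",
    "small_sample_correction",
    "SCORE_FLOOR",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: Finite stand-in for log2(0) when a zero-count base is scored with
#: pseudocount 0.  Keeps sorting and thresholding well defined.
SCORE_FLOOR = -30.0

UNIFORM_BACKGROUND = np.full(4, 0.25)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def small_sample_correction(n: int) -> float:
    """Approximate small-sample bias e(n) of the information estimate, in bits.

    Uses the first-order form (|alphabet| - 1) / (2 ln2 n) for the 4-letter
    DNA alphabet.  ``n`` is the effective number of aligned sites.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    return 3.0 / (2.0 * math.log(2) * n)


@dataclass(frozen=True)
class SiteSet:
    """A fixed-width alignment of DNA binding sites.

    Parameters
    ----------
    sites:
        Aligned site sequences; all the same length, alphabet ACGT.
    ids:
        Optional labels, one per site.
    symmetrized:
        Records whether reverse complements were appended to the original
        sites (set by :func:`build_site_matrix`; informational).
    """

    sites: tuple[str, ...]
    ids: tuple[str, ...] | None = None
    symmetrized: bool = False

    def __init__(self, sites: Iterable[str], ids: Iterable[str] | None = None,
                 symmetrized: bool = False):
        sites = tuple(s.upper() for s in sites)
        if not sites:
            raise ValueError("a SiteSet needs at least one site")
        width = len(sites[0])
        if width < 1:
            raise ValueError("sites must have width >= 1")
        for s in sites:
            if len(s) != width:
                raise ValueError(
                    f"ragged site lengths: expected {width}, got {len(s)} ({s!r})")
            if not re.fullmatch(r"[ACGT]+", s):
                raise ValueError(f"invalid characters in site {s!r}")
        object.__setattr__(self, "sites", sites)
        object.__setattr__(self, "ids", tuple(ids) if ids is not None else None)
        object.__setattr__(self, "symmetrized", bool(symmetrized))
        if self.ids is not None and len(self.ids) != len(sites):
            raise ValueError("ids and sites must have the same length")

    @property
    def width(self) -> int:
        return len(self.sites[0])

    def __len__(self) -> int:
        return len(self.sites)

    def with_complements(self) -> "SiteSet":
        """Return a new set with the reverse complement of every site appended."""
        rc = tuple(reverse_complement(s) for s in self.sites)
        ids = None
        if self.ids is not None:
            ids = self.ids + tuple(f"{i}_rc" for i in self.ids)
        return SiteSet(self.sites + rc, ids=ids, symmetrized=True)

    def counts(self) -> np.ndarray:
        """Base counts per position, shape (width, 4) ordered ACGT."""
        arr = np.zeros((self.width, 4), dtype=float)
        for s in self.sites:
            for l, b in enumerate(s):
                arr[l, _BASE_INDEX[b]] += 1
        return arr


@dataclass
class InformationModel:
    """A per-position, per-base weight matrix in bits.

    Attributes
    ----------
    riw:
        (width, 4) array of bits, columns ordered A, C, G, T.
    freqs:
        The (pseudocounted) base frequencies the weights were derived from.
    background:
        Background base probabilities, length 4, summing to 1.
    n_sites:
        Effective number of training sites (after symmetrization).
    pseudocount:
        Pseudocount added per base per column before normalizing.
    correction_enabled / e_n:
        Whether the small-sample correction was applied and its value in bits.
    symmetrized:
        Whether reverse complements were appended before counting.
    """

    riw: np.ndarray
    freqs: np.ndarray
    background: np.ndarray
    n_sites: int
    pseudocount: float = 0.5
    correction_enabled: bool = False
    e_n: float = 0.0
    symmetrized: bool = False
    name: str = "model"

    @property
    def width(self) -> int:
        return self.riw.shape[0]

    def score(self, window: str, ambiguity: str = "reject") -> float:
        """Individual information R_i of ``window`` in bits.

        ``ambiguity`` controls non-ACGT characters: ``"reject"`` raises,
        ``"neutral"`` scores them as an uninformative 0-bit contribution.
        """
        return score_site(self, window, ambiguity=ambiguity)

    def per_position_information(self) -> np.ndarray:
        return per_position_information(self)

    # --- serialization ------------------------------------------------

    def to_tsv(self, path) -> None:
        """Write the matrix as TSV with a metadata header.

        Rows are positions 1..width, columns A, C, G, T in bits.
        """
        bg = ",".join(f"{p:.10g}" for p in self.background)
        with open(path, "w") as fh:
            fh.write(f"# argbox information model: {self.name}\n")
            fh.write(
                f"# n_sites={self.n_sites} pseudocount={self.pseudocount:.10g} "
                f"correction={int(self.correction_enabled)} e_n={self.e_n:.10g} "
                f"symmetrized={int(self.symmetrized)} background={bg}\n")
            fh.write("pos\tA\tC\tG\tT\n")
            for l in range(self.width):
                vals = "\t".join(f"{v:.10g}" for v in self.riw[l])
                fh.write(f"{l + 1}\t{vals}\n")

    @classmethod
    def from_tsv(cls, path) -> "InformationModel":
        meta: dict[str, str] = {}
        name = "model"
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("# argbox information model:"):
                    name = line.split(":", 1)[1].strip()
                elif line.startswith("#"):
                    for tok in line[1:].split():
                        if "=" in tok:
                            k, v = tok.split("=", 1)
                            meta[k] = v
                elif line and not line.startswith("pos"):
                    rows.append([float(x) for x in line.split("\t")[1:5]])
        riw = np.asarray(rows, dtype=float)
        background = np.array([float(x) for x in meta["background"].split(",")])
        e_n = float(meta.get("e_n", 0.0))
        # frequencies are recovered from the weights; floored entries map to 0
        freqs = background[None, :] * np.exp2(riw + e_n)
        freqs[riw <= SCORE_FLOOR] = 0.0
        return cls(
            riw=riw,
            freqs=freqs,
            background=background,
            n_sites=int(meta["n_sites"]),
            pseudocount=float(meta.get("pseudocount", 0.0)),
            correction_enabled=bool(int(meta.get("correction", 0))),
            e_n=e_n,
            symmetrized=bool(int(meta.get("symmetrized", 0))),
            name=name,
        )


@dataclass
class TandemModel:
    """Two copies of a box matrix joined by a neutral spacer.

    The spacer positions contribute exactly 0 bits, so the tandem score of
    a window is the box score of its first ``L`` nt plus the box score of
    its last ``L`` nt.
    """

    box: InformationModel
    spacer: int

    def __post_init__(self):
        if self.spacer < 0:
            raise ValueError("spacer must be >= 0")

    @property
    def width(self) -> int:
        return 2 * self.box.width + self.spacer

    @property
    def name(self) -> str:
        return f"{self.box.name}_tandem{self.spacer}"

    def score(self, window: str, ambiguity: str = "reject") -> float:
        if len(window) != self.width:
            raise ValueError(
                f"window length {len(window)} != tandem width {self.width}")
        L = self.box.width
        return (self.box.score(window[:L], ambiguity=ambiguity)
                + self.box.score(window[-L:], ambiguity=ambiguity))


@dataclass(frozen=True)
class ScanHit:
    """One scored window from a scan, in forward coordinates.

    ``window_seq`` is the matched sequence read on the hit strand, so its
    score under the model always equals ``ri``.
    """

    seq_id: str
    offset: int
    strand: str
    ri: float
    window_seq: str


def build_site_matrix(
    sites: SiteSet,
    *,
    symmetrize: bool = True,
    background: Sequence[float] | None = None,
    pseudocount: float = 0.5,
    correction: bool = False,
    name: str = "model",
) -> InformationModel:
    """Build a weight matrix (bits) from an aligned site set.

    Parameters
    ----------
    sites:
        The training alignment.
    symmetrize:
        Append the reverse complement of every site before counting
        (appropriate for palindromic operators); the resulting matrix is
        exactly reverse-complement symmetric.
    background:
        Per-base background probabilities (A, C, G, T); default uniform,
        which gives the conventional 2-bit per-position ceiling.
    pseudocount:
        Added to every base count in every column.  With pseudocount 0 a
        zero-count base receives the finite floor :data:`SCORE_FLOOR`
        instead of -infinity.
    correction:
        Apply the small-sample correction ``e(n)`` (subtracted from every
        matrix entry).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if symmetrize:
        sites = sites.with_complements()
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    if bg.shape != (4,) or np.any(bg <= 0) or abs(bg.sum() - 1.0) > 1e-8:
        raise ValueError("background must be 4 positive probabilities summing to 1")

    counts = sites.counts()
    n = len(sites)
    freqs = (counts + pseudocount) / (n + 4.0 * pseudocount)
    e_n = small_sample_correction(n) if correction else 0.0
    with np.errstate(divide="ignore"):
        riw = np.log2(freqs / bg[None, :]) - e_n
    riw[freqs == 0] = SCORE_FLOOR
    return InformationModel(
        riw=riw,
        freqs=freqs,
        background=bg,
        n_sites=n,
        pseudocount=pseudocount,
        correction_enabled=correction,
        e_n=e_n,
        symmetrized=sites.symmetrized,
        name=name,
    )


def score_site(model: InformationModel, window: str, ambiguity: str = "reject") -> float:
    """Sum of the matrix entries of ``window``: its individual information R_i."""
    if len(window) != model.width:
        raise ValueError(
            f"window length {len(window)} != model width {model.width}")
    window = window.upper()
    total = 0.0
    for l, b in enumerate(window):
        idx = _BASE_INDEX.get(b)
        if idx is None:
            if ambiguity == "neutral":
                continue  # uninformative position: 0 bits
            raise ValueError(f"ambiguous base {b!r} at position {l}")
        total += model.riw[l, idx]
    return total


def make_tandem(model: InformationModel, spacer: int) -> TandemModel:
    """Duplicate a box matrix around ``spacer`` neutral positions."""
    return TandemModel(box=model, spacer=spacer)


def rsequence(model: InformationModel, sites: SiteSet) -> float:
    """Mean R_i of ``sites`` under ``model``.

    On the model's own training set with pseudocount 0 and no correction
    this equals the alignment's total information content
    ``sum_l (2 - H(l))``.
    """
    if sites.width != model.width:
        raise ValueError("site width does not match model width")
    return float(np.mean([score_site(model, s) for s in sites.sites]))


def per_position_information(model: InformationModel) -> np.ndarray:
    """Per-position information in bits (logo heights).

    Computed as ``sum_b f(b,l) * riw(b,l)`` which, under the uniform
    background, is ``2 - H(l) - e(n)``.  Zero-frequency floored entries
    contribute 0.
    """
    contrib = np.where(model.freqs > 0, model.freqs * model.riw, 0.0)
    return contrib.sum(axis=1)


# --- scanning ---------------------------------------------------------

def _effective_weights(model: InformationModel | TandemModel) -> np.ndarray:
    """Per-position weights of a box or tandem model as one flat matrix."""
    if isinstance(model, TandemModel):
        L = model.box.width
        W = np.zeros((model.width, 4))
        W[:L] = model.box.riw
        W[L + model.spacer:] = model.box.riw
        return W
    return model.riw


def _encode(sequence: str) -> np.ndarray:
    """Map a DNA string to integer codes 0..3 (ACGT); 4 for anything else."""
    table = np.full(256, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def _window_scores(codes: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Score every window of width len(W); windows with non-ACGT get -inf."""
    Lw = W.shape[0]
    n_win = codes.size - Lw + 1
    if n_win <= 0:
        return np.empty(0)
    # 5th column: any ambiguous base poisons the whole window
    W5 = np.hstack([W, np.full((Lw, 1), -np.inf)])
    scores = np.zeros(n_win)
    for l in range(Lw):
        scores += W5[l, codes[l:l + n_win]]
    return scores


def scan(
    model: InformationModel | TandemModel,
    sequence: str,
    threshold: float,
    *,
    seq_id: str = "seq",
    strands: str = "both",
    dedupe: bool = False,
) -> list[ScanHit]:
    """Report every window with R_i >= ``threshold``.

    Both strands may be scanned; reverse-strand hits are reported at their
    forward-coordinate offset with strand ``"-"`` and a reverse-complemented
    ``window_seq``.  Hits are sorted by (offset, strand).  Windows that
    contain non-ACGT characters are never reported.  With ``dedupe=True``
    a ``-`` hit is dropped when a ``+`` hit with an identical score exists
    at the same offset (the mirrored locus of a symmetric model).
    """
    if strands not in {"+", "-", "both"}:
        raise ValueError(f"invalid strand selector {strands!r}")
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    W = _effective_weights(model)
    codes = _encode(sequence)
    sequence = sequence.upper()
    Lw = W.shape[0]
    hits: list[ScanHit] = []
    if len(sequence) < Lw:
        return hits

    if strands in {"+", "both"}:
        fwd = _window_scores(codes, W)
        for o in np.flatnonzero(fwd >= threshold):
            o = int(o)
            hits.append(ScanHit(seq_id, o, "+", float(fwd[o]),
                                sequence[o:o + Lw]))
    if strands in {"-", "both"}:
        # scoring the reverse complement of each forward window is the same
        # as scoring the forward window with the reverse-complemented matrix
        Wrc = W[::-1, ::-1]
        rev = _window_scores(codes, Wrc)
        for o in np.flatnonzero(rev >= threshold):
            o = int(o)
            hits.append(ScanHit(seq_id, o, "-", float(rev[o]),
                                reverse_complement(sequence[o:o + Lw])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    if dedupe and strands == "both":
        plus = {(h.offset, h.ri) for h in hits if h.strand == "+"}
        hits = [h for h in hits
                if h.strand == "+" or (h.offset, h.ri) not in plus]
    return hits
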