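"""Regulatory-feature annotation of transcript UTRs.

Scanners for the sequence elements that modulate cap-dependent translation
initiation and mRNA stability:

* **TOP / TOP-like motifs** — a terminal oligopyrimidine tract: a cytosine at
  the 5' end of the mRNA followed by an uninterrupted pyrimidine run.  mRNAs
  carrying the tract at positions 2-5 instead of position 1 are called
  TOP-like.
* **uORFs** — upstream open reading frames: an AUG with its first base in the
  5'UTR whose reading frame reaches an in-frame stop codon before the end of
  the main CDS, with a minimum length (start through stop codon) of 9 nt.
* **AREs** — AU-rich elements in the 3'UTR, here the 9-mer
  ``TATTTAT[AT][AT]`` counted non-overlapping, leftmost first.
* **TISU** — Translation Initiator of Short UTR, tested either by membership
  in a curated gene list or by matching the ``SAASATGGCGGC`` consensus
  spanning the start codon.
* **5'UTR structure** — minimum free energy from RNAfold when available, or a
  built-in base-pair-maximisation proxy (nested Watson-Crick/GU pairs,
  hairpin loops of at least 3 nt) computed by dynamic programming.

All scanners work on DNA alphabet internally; U is mapped to T on input.
"""

from __future__ import annotations

import logging
import re
import shutil
import subprocess
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from numba import njit

logger = logging.getLogger(__name__)

STOP_CODONS = ("TAA", "TAG", "TGA")
PYRIMIDINES = "CT"
TISU_CONSENSUS = "SAASATGGCGGC"  # S = G or C; positions 5-7 are the AUG

_ARE_RE = re.compile("TATTTAT[AT][AT]")
_ATG_RE = re.compile("ATG")
_VALID = frozenset("ACGT")


def normalize_seq(seq: str) -> str:
    """Uppercase, map U->T and validate the alphabet."""
    s = seq.upper().replace("U", "T")
    if set(s) - _VALID:
        bad = sorted(set(s) - _VALID)
        raise ValueError(f"invalid characters in sequence: {bad}")
    return s


@dataclass
class TranscriptRecord:
    """Per-gene 5'UTR / CDS / 3'UTR sequences (DNA alphabet)."""

    gene_id: str
    utr5: str
    cds: str
    utr3: str

    def __post_init__(self) -> None:
        self.utr5 = normalize_seq(self.utr5)
        self.cds = normalize_seq(self.cds)
        self.utr3 = normalize_seq(self.utr3)
        if not self.cds:
            raise ValueError(f"{self.gene_id}: empty CDS")


class UORF(NamedTuple):
    """A single upstream ORF.

    ``start`` is the 0-based offset of the AUG in the 5'UTR; ``stop_end`` is
    the 0-based exclusive end of the stop codon in the concatenated
    ``utr5 + cds`` sequence; ``length`` spans start through stop inclusive.
    """

    start: int
    stop_end: int
    length: int


def scan_top(utr5: str, min_run: int = 4) -> str:
    """Classify a 5'UTR as ``TOP``, ``TOP_like`` or ``none``.

    TOP: position 1 is C followed by >= ``min_run`` consecutive pyrimidines.
    TOP-like: the same pattern starting at any of positions 2-5 (1-based).
    TOP takes precedence.
    """
    s = normalize_seq(utr5)

    def _match(p: int) -> bool:
        if p + 1 + min_run > len(s) or s[p] != "C":
            return False
        return all(c in PYRIMIDINES for c in s[p + 1 : p + 1 + min_run])

    if _match(0):
        return "TOP"
    if any(_match(p) for p in range(1, 5)):
        return "TOP_like"
    return "none"


def find_uorfs(utr5: str, cds: str, min_len: int = 9) -> list[UORF]:
    """Locate all qualifying uORFs in ``utr5`` given the downstream ``cds``.

    An ORF starts at any ATG whose first base lies within the 5'UTR and ends
    at the first in-frame stop codon; it qualifies if that stop ends strictly
    before the last base of the CDS and the total length (ATG through stop,
    inclusive) is at least ``min_len``.  Overlapping uORFs are all reported,
    sorted by start.
    """
    u = normalize_seq(utr5)
    c = normalize_seq(cds)
    seq = u + c
    n5 = len(u)
    out: list[UORF] = []
    for m in _ATG_RE.finditer(seq):
        start = m.start()
        if start >= n5:
            break
        for q in range(start + 3, len(seq) - 2, 3):
            if seq[q : q + 3] in STOP_CODONS:
                stop_end = q + 3
                # the stop must end strictly before the last base of the CDS
                if stop_end < len(seq) and stop_end - start >= min_len:
                    out.append(UORF(start, stop_end, stop_end - start))
                break
    return out


def scan_are(utr3: str) -> int:
    """Count non-overlapping ``TATTTAT[AT][AT]`` matches, leftmost first."""
    return len(_ARE_RE.findall(normalize_seq(utr3)))


def _iupac_mismatches(context: str, consensus: str = TISU_CONSENSUS) -> int:
    mism = 0
    for obs, ref in zip(context, consensus):
        if ref == "S":
            mism += obs not in "GC"
        else:
            mism += obs != ref
    return mism


def tisu_flag(
    gene_id: str,
    tisu_genes: Iterable[str] | None = None,
    utr5: str | None = None,
    cds: str | None = None,
    mode: str = "list",
    max_mismatch: int = 1,
) -> bool:
    """TISU status of a gene.

    ``mode='list'`` (default) tests membership in a curated gene list;
    ``mode='consensus'`` matches the ``SAASATGGCGGC`` consensus spanning the
    start codon (4 nt of 5'UTR + first 8 nt of CDS) allowing up to
    ``max_mismatch`` mismatches outside the invariant ATG.
    """
    if mode == "list":
        if tisu_genes is None:
            raise ValueError("list mode requires a TISU gene list")
        return gene_id in set(tisu_genes)
    if mode != "consensus":
        raise ValueError(f"unknown TISU mode {mode!r}")
    if utr5 is None or cds is None:
        raise ValueError("consensus mode requires utr5 and cds sequences")
    u, c = normalize_seq(utr5), normalize_seq(cds)
    if len(u) < 4 or len(c) < 8:
        return False
    context = u[-4:] + c[:8]
    if context[4:7] != "ATG":
        return False
    return _iupac_mismatches(context) <= max_mismatch


# --- built-in folding proxy -------------------------------------------------

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
MIN_HAIRPIN_LOOP = 3


@njit(cache=False)
def _max_pairs_dp(code: np.ndarray, allow_gu: bool) -> int:  # pragma: no cover
    n = code.shape[0]
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(MIN_HAIRPIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1, j]  # i unpaired
            for k in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
                s = code[i] + code[k]
                if s == 3 or (allow_gu and s == 5):
                    v = 1 + dp[i + 1, k - 1]
                    if k + 1 <= j:
                        v += dp[k + 1, j]
                    if v > best:
                        best = v
            dp[i, j] = best
    return int(dp[0, n - 1])


def _external_mfe(seq: str) -> float:
    exe = shutil.which("RNAfold")
    if exe is None:
        raise RuntimeError("external MFE backend requested but RNAfold not found")
    rna = seq.replace("T", "U")
    out = subprocess.run(
        [exe, "--noPS"], input=rna + "\n", capture_output=True, text=True, check=True
    ).stdout
    # last line: "structure ( -3.40)"
    m = re.search(r"\(\s*(-?\d+\.?\d*)\s*\)\s*$", out.strip().splitlines()[-1])
    if m is None:
        raise RuntimeError(f"could not parse RNAfold output: {out!r}")
    return float(m.group(1))


def utr5_mfe(
    utr5: str, backend: str = "builtin", allow_gu: bool = True, per_nt: bool = False
) -> float:
    """Structure score of a 5'UTR.

    ``backend='external'`` runs RNAfold and returns its MFE in kcal/mol.
    ``backend='builtin'`` returns ``-1.0 *`` the maximum number of nested
    Watson-Crick (and, by default, GU) base pairs with hairpin loops of at
    least 3 unpaired bases.  The builtin score is a structure proxy: it is
    monotone-comparable within a run but not on the kcal/mol scale.
    Sequences shorter than 5 nt score 0.
    """
    s = normalize_seq(utr5)
    if len(s) < 5:
        return 0.0
    if backend == "external":
        score = _external_mfe(s)
    elif backend == "builtin":
        code = np.array([_BASE_CODE[c] for c in s], dtype=np.int8)
        score = -float(_max_pairs_dp(code, allow_gu))
    else:
        raise ValueError(f"unknown MFE backend {backend!r}")
    return score / len(s) if per_nt else score


def annotate_transcripts(
    records: Sequence[TranscriptRecord],
    tisu_genes: Iterable[str] | None = None,
    min_top_run: int = 4,
    uorf_min_len: int = 9,
    mfe_backend: str = "builtin",
    tisu_mode: str = "list",
    allow_gu: bool = True,
    mfe_per_nt: bool = False,
) -> pd.DataFrame:
    """Build the per-gene feature table.

    Returns a DataFrame indexed by gene id with columns ``utr5_len``,
    ``utr5_mfe``, ``top_class``, ``n_uorf``, ``n_are`` and ``tisu``.
    Raises on duplicate gene ids.
    """
    if not len(records):
        raise ValueError("no transcript records supplied")
    ids = [r.gene_id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({g for g in ids if ids.count(g) > 1})
        raise ValueError(f"duplicate gene ids: {dup}")
    tisu_set = set(tisu_genes) if tisu_genes is not None else set()
    rows = []
    for r in records:
        if tisu_mode == "list":
            tisu = r.gene_id in tisu_set
        else:
            tisu = tisu_flag(r.gene_id, utr5=r.utr5, cds=r.cds, mode="consensus")
        rows.append(
            {
                "gene": r.gene_id,
                "utr5_len": len(r.utr5),
                "utr5_mfe": utr5_mfe(
                    r.utr5, backend=mfe_backend, allow_gu=allow_gu, per_nt=mfe_per_nt
                ),
                "top_class": scan_top(r.utr5, min_run=min_top_run),
                "n_uorf": len(find_uorfs(r.utr5, r.cds, min_len=uorf_min_len)),
                "n_are": scan_are(r.utr3),
                "tisu": tisu,
            }
        )
    return pd.DataFrame(rows).set_index("gene")
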