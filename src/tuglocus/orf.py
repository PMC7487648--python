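"""ORF discovery with non-canonical starts, conservation pairing and peptide properties.

Short ORFs hidden in annotated noncoding transcripts often initiate at
near-cognate codons; the scanner therefore accepts AUG, CUG and UUG starts
(the initiator always translating as Met, matching initiator-tRNA
behavior).  Within each reading frame every stop codon is paired with the
5'-most allowed start after the previous stop, giving one maximal ORF per
stop per frame.  Cross-species ORF pairs are anchored on conserved start /
stop alignment columns of a nucleotide alignment of the parent sequences,
with global peptide alignment identity attached.  Peptide properties
(average molecular weight, net charge at pH 7) use standard residue masses
and the EMBOSS pKa set.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqUtils import molecular_weight

STOP_CODONS = {"TAA", "TAG", "TGA"}
DEFAULT_STARTS = ("AUG", "CUG", "UUG")
DEFAULT_MIN_AA = 25
AA20 = set("ACDEFGHIKLMNPQRSTVWY")

# EMBOSS pKa values for ionizable groups
_PKA_POS = {"Nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
_PKA_NEG = {"Cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class OrfRecord:
    """One open reading frame on a transcript sequence (coordinates in nt, 0-based).

    ``stop`` is the half-open end of the stop codon, so (stop - start) is a
    multiple of 3 and the peptide (initiator included, stop excluded) has
    (stop - start) / 3 - 1 residues.
    """

    seq_id: str
    frame: int
    start: int
    stop: int
    start_codon: str  # RNA alphabet: AUG / CUG / UUG
    peptide: str
    strand: str = "+"

    @property
    def length_aa(self) -> int:
        return (self.stop - self.start) // 3 - 1


@dataclass(frozen=True)
class PeptideProperties:
    length_aa: int
    molecular_weight: float  # average isotopic mass, Da
    net_charge: float  # at pH 7.0


def _normalize_nt(seq: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide symbols {sorted(bad)}")
    return s


def _translate(dna: str) -> str:
    pep = str(Seq(dna).translate(table=1))
    return "M" + pep[1:]  # initiator (canonical or near-cognate) reads as Met


def find_orfs(
    seq: str,
    seq_id: str = "seq",
    starts: tuple[str, ...] = DEFAULT_STARTS,
    min_aa: int = DEFAULT_MIN_AA,
    both_strands: bool = False,
) -> list[OrfRecord]:
    """Scan all frames for maximal ORFs with the allowed start codons.

    For every frame, each stop codon is paired with the 5'-most in-frame
    allowed start after the previous stop (one maximal ORF per stop per
    frame); all allowed start codons rank equally.  Codons containing N
    never match a start or stop.  ORFs shorter than ``min_aa`` residues are
    dropped.  With ``both_strands`` the reverse complement is scanned too,
    coordinates reported on the reverse-complemented sequence.
    """
    if not seq:
        raise ValueError("empty sequence")
    dna = _normalize_nt(seq)
    start_dna = {s.upper().replace("U", "T") for s in starts}
    records: list[OrfRecord] = []

    def _scan(s: str, strand: str) -> None:
        for frame in range(3):
            pending: int | None = None
            for i in range(frame, len(s) - 2, 3):
                codon = s[i : i + 3]
                if "N" in codon:
                    continue
                if codon in STOP_CODONS:
                    if pending is not None:
                        aa_len = (i + 3 - pending) // 3 - 1
                        if aa_len >= min_aa:
                            records.append(
                                OrfRecord(
                                    seq_id=seq_id,
                                    frame=frame,
                                    start=pending,
                                    stop=i + 3,
                                    start_codon=s[pending : pending + 3].replace("T", "U"),
                                    peptide=_translate(s[pending:i]),
                                    strand=strand,
                                )
                            )
                        pending = None
                elif pending is None and codon in start_dna:
                    pending = i

    _scan(dna, "+")
    if both_strands:
        _scan(dna.translate(_COMPLEMENT)[::-1], "-")
    return sorted(records, key=lambda r: (r.strand, r.start))


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def align_peptides(pep_a: str, pep_b: str) -> tuple[tuple[str, str], float]:
    """Global alignment (BLOSUM62, affine 11/1) and percent identity.

    Identity = identical columns / total alignment columns x 100, gaps
    counting as columns.  Symmetric in its arguments.
    """
    for pep in (pep_a, pep_b):
        if not pep:
            raise ValueError("empty peptide")
        bad = set(pep) - AA20
        if bad:
            raise ValueError(f"non-amino-acid symbols {sorted(bad)}")
    aln = _make_aligner().align(pep_a, pep_b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(row_a, row_b) if x == y and x != "-")
    identity = 100.0 * matches / len(row_a)
    return (row_a, row_b), identity


@dataclass(frozen=True)
class ConservedOrfPair:
    orf_a: OrfRecord
    orf_b: OrfRecord
    aa_identity: float
    start_conserved: bool
    stop_conserved: bool
    flagged: bool  # identity above the conservation threshold


def _seq_to_alignment_columns(gapped: str) -> list[int]:
    cols = []
    for col, ch in enumerate(gapped):
        if ch != "-":
            cols.append(col)
    return cols


def conserved_orf_pairs(
    orfs_a: list[OrfRecord],
    orfs_b: list[OrfRecord],
    nt_alignment: tuple[str, str],
    identity_threshold: float = 70.0,
    codon_tolerance_nt: int = 3,
) -> list[ConservedOrfPair]:
    """Pair ORFs across species on conserved start/stop alignment columns.

    Two ORFs are paired when their start codons (or their stop codons) fall
    on the same columns of the parent-sequence nucleotide alignment within
    one codon of tolerance; conservation of each anchor is reported
    separately, and pairs with amino-acid identity at or above
    ``identity_threshold`` are flagged as conserved.
    """
    gapped_a, gapped_b = nt_alignment
    if len(gapped_a) != len(gapped_b):
        raise ValueError("alignment rows have different lengths")
    cols_a = _seq_to_alignment_columns(gapped_a)
    cols_b = _seq_to_alignment_columns(gapped_b)
    pairs: list[ConservedOrfPair] = []
    for oa in orfs_a:
        if oa.stop > len(cols_a):
            raise ValueError(f"ORF {oa.seq_id}:{oa.start} outside aligned span")
        for ob in orfs_b:
            if ob.stop > len(cols_b):
                raise ValueError(f"ORF {ob.seq_id}:{ob.start} outside aligned span")
            d_start = abs(cols_a[oa.start] - cols_b[ob.start])
            d_stop = abs(cols_a[oa.stop - 3] - cols_b[ob.stop - 3])
            start_ok = d_start <= codon_tolerance_nt
            stop_ok = d_stop <= codon_tolerance_nt
            if not (start_ok or stop_ok):
                continue
            _, identity = align_peptides(oa.peptide, ob.peptide)
            pairs.append(
                ConservedOrfPair(
                    orf_a=oa,
                    orf_b=ob,
                    aa_identity=identity,
                    start_conserved=start_ok,
                    stop_conserved=stop_ok,
                    flagged=identity >= identity_threshold,
                )
            )
    return sorted(pairs, key=lambda p: -p.aa_identity)


def peptide_properties(pep: str) -> PeptideProperties:
    """Average molecular weight and Henderson-Hasselbalch net charge at pH 7.

    Charge sums the protonated fractions of the N-terminus and basic side
    chains (K, R, H) minus the deprotonated fractions of the C-terminus and
    acidic/ionizable side chains (D, E, C, Y), all with EMBOSS pKa values.
    """
    if not pep:
        raise ValueError("empty peptide has no defined properties")
    bad = set(pep) - AA20
    if bad:
        raise ValueError(f"unknown residue symbols {sorted(bad)}")
    mw = molecular_weight(pep, seq_type="protein")
    ph = 7.0
    charge = 1.0 / (1.0 + 10 ** (ph - _PKA_POS["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (_PKA_NEG["Cterm"] - ph))
    for aa in pep:
        if aa in _PKA_POS:
            charge += 1.0 / (1.0 + 10 ** (ph - _PKA_POS[aa]))
        elif aa in _PKA_NEG:
            charge -= 1.0 / (1.0 + 10 ** (_PKA_NEG[aa] - ph))
    return PeptideProperties(
        length_aa=len(pep), molecular_weight=float(mw), net_charge=float(charge)
    )


def verify_antisense_probe(
    probe_rna: str, cdna: str
) -> tuple[bool, list[tuple[int, int]], str]:
    """Check a riboprobe against its source cDNA.

    True iff the probe's reverse complement (U -> T) occurs as an exact
    substring of the cDNA (an antisense probe), or -- for probes published
    as the sense sequence -- the probe's U -> T form itself occurs.  Returns
    (matched, hit coordinates on the cDNA, orientation).
    """
    if not probe_rna or not cdna:
        raise ValueError("empty sequence")
    probe = _normalize_nt(probe_rna)
    target = _normalize_nt(cdna)
    rc = probe.translate(_COMPLEMENT)[::-1]

    def _hits(sub: str) -> list[tuple[int, int]]:
        hits = []
        i = target.find(sub)
        while i != -1:
            hits.append((i, i + len(sub)))
            i = target.find(sub, i + 1)
        return hits

    anti = _hits(rc)
    if anti:
        return True, anti, "antisense"
    sense = _hits(probe)
    if sense:
        return True, sense, "sense"
    return False, [], "none"
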