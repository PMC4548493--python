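"""Substitution scoring: BLOSUM62, Grantham distance, SIFT classes and
physicochemical change types.

Both matrices ship as embedded constants so the package has no runtime
data dependencies.  Class thresholds:

* BLOSUM62 — score >= 0 conservative, == -1 non-conservative,
  <= -2 radical;
* Grantham — 0-60 conservative, > 60 non-conservative, > 100 radical;
* SIFT — <= 0.10 intolerant, > 0.10 tolerant.

Amino acids fall into four physicochemical groups (polar, hydrophobic,
positively charged, negatively charged); an ordered substitution maps to
one change type: hydrophobicity loss, charge loss, polarity loss, charge
change, or minor.  Gains (polar -> charged) and within-group swaps count
as minor by default; the mapping is overridable.
"""

from __future__ import annotations

from dataclasses import dataclass

from .aminoacids import one_letter

_AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

_BLOSUM62_ROWS = """
A   4  -1  -2  -2   0  -1  -1   0  -2  -1  -1  -1  -1  -2  -1   1   0  -3  -2   0
R  -1   5   0  -2  -3   1   0  -2   0  -3  -2   2  -1  -3  -2  -1  -1  -3  -2  -3
N  -2   0   6   1  -3   0   0   0   1  -3  -3   0  -2  -3  -2   1   0  -4  -2  -3
D  -2  -2   1   6  -3   0   2  -1  -1  -3  -4  -1  -3  -3  -1   0  -1  -4  -3  -3
C   0  -3  -3  -3   9  -3  -4  -3  -3  -1  -1  -3  -1  -2  -3  -1  -1  -2  -2  -1
Q  -1   1   0   0  -3   5   2  -2   0  -3  -2   1   0  -3  -1   0  -1  -2  -1  -2
E  -1   0   0   2  -4   2   5  -2   0  -3  -3   1  -2  -3  -1   0  -1  -3  -2  -2
G   0  -2   0  -1  -3  -2  -2   6  -2  -4  -4  -2  -3  -3  -2   0  -2  -2  -3  -3
H  -2   0   1  -1  -3   0   0  -2   8  -3  -3  -1  -2  -1  -2  -1  -2  -2   2  -3
I  -1  -3  -3  -3  -1  -3  -3  -4  -3   4   2  -3   1   0  -3  -2  -1  -3  -1   3
L  -1  -2  -3  -4  -1  -2  -3  -4  -3   2   4  -2   2   0  -3  -2  -1  -2  -1   1
K  -1   2   0  -1  -3   1   1  -2  -1  -3  -2   5  -1  -3  -1   0  -1  -3  -2  -2
M  -1  -1  -2  -3  -1   0  -2  -3  -2   1   2  -1   5   0  -2  -1  -1  -1  -1   1
F  -2  -3  -3  -3  -2  -3  -3  -3  -1   0   0  -3   0   6  -4  -2  -2   1   3  -1
P  -1  -2  -2  -1  -3  -1  -1  -2  -2  -3  -3  -1  -2  -4   7  -1  -1  -4  -3  -2
S   1  -1   1   0  -1   0   0   0  -1  -2  -2   0  -1  -2  -1   4   1  -3  -2  -2
T   0  -1   0  -1  -1  -1  -1  -2  -2  -1  -1  -1  -1  -2  -1   1   5  -2  -2   0
W  -3  -3  -4  -4  -2  -2  -3  -2  -2  -3  -2  -3  -1   1  -4  -3  -2  11   2  -3
Y  -2  -2  -2  -3  -2  -1  -2  -3   2  -1  -1  -2  -1   3  -3  -2  -2   2   7  -1
V   0  -3  -3  -3  -1  -2  -2  -3  -3   3   1  -2   1  -1  -2  -2   0  -3  -1   4
"""

# Published integer Grantham distances.  The printed table deviates from
# the underlying composition/polarity/volume formula by at most one unit
# of rounding, except Asp-Trp (printed 181); the printed values are used.
_GRANTHAM_ROWS = """
A    0  112  111  126  195   91  107   60   86   94   96  106   84  113   27   99   58  148  112   64
R  112    0   86   96  180   43   54  125   29   97  102   26   91   97  103  110   71  101   77   96
N  111   86    0   23  139   46   42   80   68  149  153   94  142  158   91   46   65  174  143  133
D  126   96   23    0  154   61   45   94   81  168  172  101  160  177  108   65   85  181  160  152
C  195  180  139  154    0  154  170  159  174  198  198  202  196  205  169  112  149  215  194  192
Q   91   43   46   61  154    0   29   87   24  109  113   53  101  116   76   68   42  130   99   96
E  107   54   42   45  170   29    0   98   40  134  138   56  126  140   93   80   65  152  122  121
G   60  125   80   94  159   87   98    0   98  135  138  127  127  153   42   56   59  184  147  109
H   86   29   68   81  174   24   40   98    0   94   99   32   87  100   77   89   47  115   83   84
I   94   97  149  168  198  109  134  135   94    0    5  102   10   21   95  142   89   61   33   29
L   96  102  153  172  198  113  138  138   99    5    0  107   15   22   98  145   92   61   36   32
K  106   26   94  101  202   53   56  127   32  102  107    0   95  102  103  121   78  110   85   97
M   84   91  142  160  196  101  126  127   87   10   15   95    0   28   87  135   81   67   36   21
F  113   97  158  177  205  116  140  153  100   21   22  102   28    0  114  155  103   40   22   50
P   27  103   91  108  169   76   93   42   77   95   98  103   87  114    0   74   38  147  110   68
S   99  110   46   65  112   68   80   56   89  142  145  121  135  155   74    0   58  177  144  124
T   58   71   65   85  149   42   65   59   47   89   92   78   81  103   38   58    0  128   92   69
W  148  101  174  181  215  130  152  184  115   61   61  110   67   40  147  177  128    0   37   88
Y  112   77  143  160  194   99  122  147   83   33   36   85   36   22  110  144   92   37    0   55
V   64   96  133  152  192   96  121  109   84   29   32   97   21   50   68  124   69   88   55    0
"""


def _parse_matrix(rows: str) -> dict[tuple[str, str], int]:
    out: dict[tuple[str, str], int] = {}
    for line in rows.strip().splitlines():
        parts = line.split()
        aa, values = parts[0], [int(v) for v in parts[1:]]
        assert len(values) == 20
        for bb, v in zip(_AA_ORDER, values):
            out[(aa, bb)] = v
    assert len(out) == 400
    return out


BLOSUM62: dict[tuple[str, str], int] = _parse_matrix(_BLOSUM62_ROWS)
GRANTHAM: dict[tuple[str, str], int] = _parse_matrix(_GRANTHAM_ROWS)

# physicochemical groups
POLAR = frozenset("QNHSTYCMW")
HYDROPHOBIC = frozenset("AILFVPG")
POSITIVE = frozenset("RK")
NEGATIVE = frozenset("DE")


def aa_class(aa: str) -> str:
    aa = one_letter(aa)
    if aa in POLAR:
        return "polar"
    if aa in HYDROPHOBIC:
        return "hydrophobic"
    if aa in POSITIVE:
        return "charged_positive"
    return "charged_negative"


#: (wt_class, mut_class) -> change type.  Charged classes are distinct;
#: transitions not listed are "minor" (within-class swaps and gains).
CHANGE_TYPE_MAP: dict[tuple[str, str], str] = {
    ("hydrophobic", "polar"): "hydrophobicity_loss",
    ("hydrophobic", "charged_positive"): "hydrophobicity_loss",
    ("hydrophobic", "charged_negative"): "hydrophobicity_loss",
    ("charged_positive", "polar"): "charge_loss",
    ("charged_positive", "hydrophobic"): "charge_loss",
    ("charged_negative", "polar"): "charge_loss",
    ("charged_negative", "hydrophobic"): "charge_loss",
    ("polar", "hydrophobic"): "polarity_loss",
    ("charged_positive", "charged_negative"): "charge_change",
    ("charged_negative", "charged_positive"): "charge_change",
}


@dataclass(frozen=True)
class SubstitutionScores:
    blosum62: int
    blosum_class: str
    grantham: int
    grantham_class: str
    sift_class: str  # "intolerant" | "tolerant" | "missing"


@dataclass(frozen=True)
class PhyschemChange:
    wt_class: str
    mut_class: str
    change_type: str

    @property
    def is_major(self) -> bool:
        return self.change_type != "minor"


def blosum62_score(wt: str, mut: str) -> tuple[int, str]:
    """BLOSUM62 score and its tolerance class for a substitution."""
    score = BLOSUM62[(one_letter(wt), one_letter(mut))]
    if score >= 0:
        cls = "conservative"
    elif score == -1:
        cls = "non_conservative"
    else:
        cls = "radical"
    return score, cls


def grantham_distance(wt: str, mut: str) -> tuple[int, str]:
    """Grantham physicochemical distance and its class."""
    d = GRANTHAM[(one_letter(wt), one_letter(mut))]
    if d > 100:
        cls = "radical"
    elif d > 60:
        cls = "non_conservative"
    else:
        cls = "conservative"
    return d, cls


def classify_sift(score: float | None) -> str:
    """``intolerant`` for scores <= 0.10, ``tolerant`` above, ``missing``
    when no score is available."""
    if score is None or score != score:  # NaN-safe
        return "missing"
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"SIFT score outside [0, 1]: {score}")
    return "intolerant" if score <= 0.10 else "tolerant"


def physchem_change(
    wt: str,
    mut: str,
    mapping: dict[tuple[str, str], str] | None = None,
) -> PhyschemChange:
    """Physicochemical change type introduced by a substitution."""
    wc, mc = aa_class(wt), aa_class(mut)
    mapping = CHANGE_TYPE_MAP if mapping is None else mapping
    return PhyschemChange(wc, mc, mapping.get((wc, mc), "minor"))


def score_substitution(wt: str, mut: str, sift: float | None = None) -> SubstitutionScores:
    """All substitution scores for one variant in one record."""
    b, bc = blosum62_score(wt, mut)
    g, gc = grantham_distance(wt, mut)
    return SubstitutionScores(
        blosum62=b, blosum_class=bc,
        grantham=g, grantham_class=gc,
        sift_class=classify_sift(sift),
    )
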