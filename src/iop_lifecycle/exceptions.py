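"""Exceptions shared across the estimation stack."""


class CellDegenerate(Exception):
    """A country×cohort×age cell cannot support the estimator.

    Raised when the outcome has no cases (or no non-cases), when the cell is
    empty, or when the mean predicted probability is zero so the dissimilarity
    index is undefined.  In multi-cell runs this never aborts the run: the
    pipeline records the cell as missing with the reason carried here.
    """

    def __init__(self, reason: str, cell=None):
        self.reason = reason
        self.cell = cell
        msg = reason if cell is None else f"{reason} (cell: {cell})"
        super().__init__(msg)


class ShareUndefined(Exception):
    """Shapley shares are undefined because the full-model index is zero."""


class RankDeficientDesign(Exception):
    """Design matrix is rank deficient after dropping constant columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"collinear circumstance columns: {self.columns}")
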