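"""Generic container for the outcome of a statistical test."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class TestResult:
    """Outcome of a hypothesis test.

    Attributes
    ----------
    method : str
        Human-readable label of the procedure (e.g. ``"quasi-binomial GLM"``).
    statistic_name : str
        Name of the test statistic (``"F"``, ``"chi2"``, ``"t"``, ``"z"``).
    statistic : float
        Value of the test statistic.
    df : tuple
        Degrees of freedom; ``(num,)`` or ``(num, den)`` depending on the test.
    pvalue : float
        Two-sided p-value in ``[0, 1]``.
    estimate : float or None
        Effect estimate on the scale natural to the test (difference in
        proportions, model coefficient, ...).
    conf_int : tuple or None
        ``(lo, hi)`` interval for ``estimate`` when available.
    warnings : list of str
        Non-fatal issues raised during fitting (singular fit, separation, ...).
    extra : dict
        Method-specific extras (per-term tables, group estimates, ...).
    """

    method: str
    statistic_name: str
    statistic: float
    df: tuple
    pvalue: float
    estimate: float | None = None
    conf_int: tuple | None = None
    warnings: list = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0 or self.pvalue != self.pvalue):
            raise ValueError(f"p-value outside [0, 1]: {self.pvalue}")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic_name": self.statistic_name,
            "statistic": float(self.statistic),
            "df": list(self.df),
            "pvalue": float(self.pvalue),
            "estimate": None if self.estimate is None else float(self.estimate),
            "conf_int": None if self.conf_int is None else list(self.conf_int),
            "warnings": list(self.warnings),
        }
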