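"""Small assay formulas used around the screen: knockdown-validation
percent change, relative expression by the comparative-Ct method, and the
transplantation stem-cell number."""

from __future__ import annotations

from dataclasses import dataclass


def percent_change(treated: float, control: float) -> float:
    """Signed percent change of a treated readout versus control:
    100 * (treated - control) / control.  Reductions come out negative;
    prose of the form "reduced by X%" reports the magnitude."""
    if control <= 0:
        raise ValueError("control readout must be > 0")
    return 100.0 * (treated - control) / control


@dataclass(frozen=True)
class QpcrRecord:
    """Cycle thresholds for one comparative-Ct quantification: target and
    reference gene, in treated and control samples."""

    ct_target_treated: float
    ct_ref_treated: float
    ct_target_control: float
    ct_ref_control: float

    @property
    def ddct(self) -> float:
        return (self.ct_target_treated - self.ct_ref_treated) - (
            self.ct_target_control - self.ct_ref_control
        )


def ddct_fold_change(record: QpcrRecord) -> float:
    """Relative expression 2**(-ΔΔCt), assuming 100% amplification
    efficiency."""
    return 2.0 ** (-record.ddct)


def stem_cell_number(colonies: float, cells_injected: float) -> float:
    """Transplantation-derived stem cell number: colonies of donor-derived
    spermatogenesis per 1e5 cells injected."""
    if cells_injected <= 0:
        raise ValueError("cells_injected must be > 0")
    if colonies < 0:
        raise ValueError("colonies must be >= 0")
    return colonies * 1e5 / cells_injected
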