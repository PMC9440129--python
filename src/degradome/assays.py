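"""Closed-form companion assay metrics: receptor internalisation,
autophagic flux and qPCR relative expression.

These are deliberately plain formula utilities with no statistics
attached; batch application over a table of readings is left to the
caller (or the CLI's batch mode).
"""

from __future__ import annotations


def percent_internalised(mfi_sample: float, mfi_ice90: float) -> float:
    """Percent of surface receptor internalised relative to the ice control.

    ``mfi_ice90`` is the mean fluorescence intensity of cells held 90 min
    on ice (no internalisation, 0% by construction):

        % internalised = 100 - (MFI_sample / MFI_ice90) * 100
    """
    if mfi_ice90 <= 0:
        raise ValueError("ice-control MFI must be > 0")
    return 100.0 - (mfi_sample / mfi_ice90) * 100.0


def autophagic_flux(mfi_bafa1: float, mfi_vehicle: float) -> float:
    """Autophagic flux from LC3-II MFI: (BafA1 - vehicle) / vehicle.

    Negative flux (BafA1 below vehicle) is returned as-is.
    """
    if mfi_vehicle <= 0:
        raise ValueError("vehicle MFI must be > 0")
    return (mfi_bafa1 - mfi_vehicle) / mfi_vehicle


def ddct_fold_change(
    ct_target_test: float,
    ct_ref_test: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression by the delta-delta-Ct method, 2^(-ddCt).

    The reference gene (e.g. Gapdh) normalises loading within each
    condition; the control condition anchors the fold change at 1.
    """
    ddct = (ct_target_test - ct_ref_test) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))
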