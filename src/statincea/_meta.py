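"""Package version and willingness-to-pay reference thresholds."""

__version__ = "0.1.0"

#: Indonesian stated willingness to pay for life-saving disease (IDR/QALY).
WTP_LIFE_SAVING = 192_514_839.0
#: Three times Indonesian GDP per capita (IDR/QALY).
WTP_3X_GDP = 206_319_831.79
DEFAULT_WTP_THRESHOLDS = (WTP_LIFE_SAVING, WTP_3X_GDP)
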