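"""Shared constants."""

# Average weeks per year used to convert week-denominated utility integrals
# into QALYs (365.25 / 7 ≈ 52.18).
WEEKS_PER_YEAR: float = 365.25 / 7.0

# Default assessment schedule (weeks after start of treatment).
DEFAULT_ASSESSMENT_WEEKS: tuple[int, ...] = (0, 10, 20, 30)

# Resource-use recall window of the cost questionnaire, in weeks.
RECALL_WINDOW_WEEKS: float = 4.0

# Column prefix for per-item resource-use counts in the long-format dataset.
RESOURCE_PREFIX = "ru_"

ARM_BLENDED = "blended"
ARM_STANDARD = "standard"
ARMS = (ARM_BLENDED, ARM_STANDARD)
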