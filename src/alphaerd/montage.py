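"""10-20 montage constants shared across the package."""

#: The 16 scalp positions of the recording montage, in acquisition order.
CHANNELS_16 = (
    "O2", "O1", "P4", "P3", "C4", "C3", "F4", "F3",
    "FP2", "FP1", "T6", "T5", "T4", "T3", "F8", "F7",
)

#: Frontal channels retained for analysis, in canonical order.
FRONTAL_CHANNELS = ("F3", "F4", "FP1", "FP2")

#: Left-hemisphere frontal channels (region Fs = mean of F3, FP1).
LEFT_FRONTAL = ("F3", "FP1")

#: Right-hemisphere frontal channels (region Fd = mean of F4, FP2).
RIGHT_FRONTAL = ("F4", "FP2")

#: Reference description; metadata only, no re-referencing is performed.
REFERENCE = "linked ears"


def normalize_label(label: str) -> str:
    """Map channel-name dialects ('Fp1', 'fp1', 'EEG FP1') to canonical upper-case."""
    lab = label.strip()
    if lab.upper().startswith("EEG "):
        lab = lab[4:]
    return lab.strip().upper()
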