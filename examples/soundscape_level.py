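"""Coarse environmental-level estimation from digital level.

Autonomous recorders report only digital amplitude. Recording a test
noise of known environmental level (here 69 dBA pink noise reads
-19 dBFS on the recorder) fixes an offset; any later recording's dBFS
then maps to an approximate dBA, valid to the extent the soundscape's
spectrum resembles the calibration noise.
"""

from ribbit import dba_offset, dbfs, estimate_dba, gen_background

offset = dba_offset(calibration_dba=69.0, calibration_dbfs=-19.0)
print(f"calibration: 69 dBA test noise read -19 dBFS -> offset {offset:.0f} dB")

soundscape = gen_background("pink", duration_s=10.0, rms_level=0.00177, seed=6)
level_dbfs = dbfs(soundscape)
level_dba = estimate_dba(soundscape, offset)
print(f"soundscape digital level: {level_dbfs:.0f} dBFS")
print(f"estimated environmental level: {level_dba:.0f} dBA")
print(
    "\nThe estimate assumes the soundscape roughly matches the calibration "
    "noise's (pink) spectrum and the same recorder gain."
)
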