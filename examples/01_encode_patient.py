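"""Encode one patient's predictors into the bit vectors the networks consume.

PSA becomes a 9-bit unsigned binary number (MSB first); Gleason score and
clinical T stage become one-hot flag vectors (9 and 8 flags respectively).
"""

from prostage import PatientRecord, encode_record

patient = PatientRecord(psa=8.7, gleason="7(3+4)", clinical_t="T2a")
enc = encode_record(patient)

print(f"PSA {patient.psa} ng/mL    -> bits  {enc.psa_bits.tolist()}  (binary of round(8.7)=9)")
print(f"Gleason {patient.gleason} -> flags {enc.gleason_flags.tolist()}  (position 4 of 9)")
print(f"Clinical {patient.clinical_t}   -> flags {enc.clinical_t_flags.tolist()}  (position 3 of 8)")
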