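"""Forearm muscle-group label dictionary.

Ten muscle-group regions of interest cover the forearm muscle compartment.
Integer labels 1..10 map to the standard abbreviations; 0 is background
(bone, subcutaneous fat and air are unlabelled).
"""

from __future__ import annotations

#: name -> integer label
MUSCLE_LABELS: dict[str, int] = {
    "ECU": 1,       # extensor carpi ulnaris
    "EDM": 2,       # extensor digiti minimi
    "ED": 3,        # extensor digitorum
    "EPL": 4,       # extensor pollicis longus
    "APL": 5,       # abductor pollicis longus
    "ECRLB_BR": 6,  # extensor carpi radialis longus/brevis + brachioradialis
    "FDP": 7,       # flexor digitorum profundus + flexor pollicis longus
    "FDS": 8,       # flexor digitorum superficialis + palmaris longus
    "FCU": 9,       # flexor carpi ulnaris
    "FCR": 10,      # flexor carpi radialis
}

LABEL_NAMES: dict[int, str] = {v: k for k, v in MUSCLE_LABELS.items()}

#: dorsal (extensor) compartment labels
DORSAL_LABELS: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
#: volar (flexor) compartment labels
VOLAR_LABELS: tuple[int, ...] = (7, 8, 9, 10)

ALL_LABELS: tuple[int, ...] = DORSAL_LABELS + VOLAR_LABELS
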