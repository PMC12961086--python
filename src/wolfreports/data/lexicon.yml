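# Valence lexicon for wolf-sighting reports (English + Italian).
# Negative terms capture fear / anger / concern / danger / emergency /
# scare and close relatives; implicit patterns are phrases that convey
# concern without using an explicit term.  The list is extensible and
# makes no claim to reproduce any particular coding protocol.
negative_terms:
  - fear
  - afraid
  - scared
  - scare
  - scary
  - frightened
  - frightening
  - terrified
  - anger
  - angry
  - furious
  - concern
  - concerned
  - worried
  - worry
  - alarmed
  - danger
  - dangerous
  - threat
  - threatening
  - emergency
  - urgent
  - attack
  - attacked
  - paura
  - spaventato
  - spaventata
  - spaventoso
  - rabbia
  - arrabbiato
  - preoccupato
  - preoccupata
  - preoccupazione
  - allarmato
  - pericolo
  - pericoloso
  - minaccia
  - emergenza
  - urgente
  - aggredito
positive_terms:
  - beautiful
  - wonderful
  - amazing
  - magnificent
  - thrilled
  - lucky
  - admire
  - admiration
  - fascinating
  - hope
  - protect
  - bellissimo
  - bellissima
  - meraviglioso
  - meravigliosa
  - stupendo
  - emozionante
  - fortunato
  - affascinante
  - proteggere
implicit_negative_patterns:
  - "there are children"
  - "can't even leave the house"
  - "cannot leave the house"
  - "come quickly"
  - "do something"
  - "too close to the houses"
  - "ci sono bambini"
  - "non possiamo uscire di casa"
  - "non si puo uscire"
  - "venite subito"
  - "fate qualcosa"
  - "troppo vicino alle case"
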