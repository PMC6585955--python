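# Functional-group database, schema version 1.
#
# Each entry names a functional group, gives a SMARTS pattern for it,
# and tags pattern-atom positions (0-based, in SMARTS atom order) as
# "bonder" slots (atoms that form a new bond during assembly) or
# "deleter" slots (atoms removed when the group reacts).  Molecules
# are matched with explicit hydrogens, so patterns spell out the H
# atoms they consume.
schema: 1
groups:
  - name: amine
    smarts: "[N]([H])[H]"
    bonder_slots: [0]          # the nitrogen forms the new bond
    deleter_slots: [1, 2]      # both N-bound hydrogens leave
  - name: aldehyde
    smarts: "[C](=[O])[H]"
    bonder_slots: [0]          # carbonyl carbon
    deleter_slots: [1]         # carbonyl oxygen leaves; the H stays
  - name: carboxylic_acid
    smarts: "[C](=[O])[O][H]"
    bonder_slots: [0]
    deleter_slots: [2, 3]      # the hydroxyl O-H leaves
  - name: amide
    smarts: "[C](=[O])[N]([H])[H]"
    bonder_slots: [0]
    deleter_slots: [2, 3, 4]   # the whole NH2 leaves
  - name: bromine
    smarts: "[*][Br]"
    bonder_slots: [0]
    deleter_slots: [1]
  - name: iodine
    smarts: "[*][I]"
    bonder_slots: [0]
    deleter_slots: [1]
  - name: alkyne
    smarts: "[C]#[C][H]"
    bonder_slots: [1]          # terminal carbon
    deleter_slots: [2]
  - name: alcohol
    smarts: "[O]([H])[#6]"
    bonder_slots: [0]
    deleter_slots: [1]
  - name: thiol
    smarts: "[S]([H])[#6]"
    bonder_slots: [0]
    deleter_slots: [1]
  - name: boronic_acid
    smarts: "[B]([O][H])[O][H]"
    bonder_slots: [0]
    deleter_slots: [1, 2, 3, 4]
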