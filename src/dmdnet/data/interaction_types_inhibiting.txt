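agonist, inhibitor
allosteric modulator, antagonist
antagonist
antagonist, activator
antagonist, agonist
antagonist, allosteric modulator
antagonist, antibody
antagonist, binder
antagonist, blocker
antagonist, inducer
antagonist, inhibitor
antagonist, inverse agonist
antagonist, ligand
antagonist, ligand, partial agonist
antagonist, multitarget
antagonist, partial agonist
antagonist, potentiator
antagonist, substrate
antibody, inhibitor
binder, inhibitor
blocker
blocker, inhibitor
cleavage
inhibitor
inhibitor, activator
inhibitor, antibody
inhibitor, inducer
inhibitor, substrate
inhibitory allosteric modulator
inhibitory allosteric modulator, antagonist
inverse agonist
ligand, inhibitor
modulator, antagonist
modulator, inhibitor
negative modulator
negative modulator, agonist
negative modulator, agonist, antagonist
negative modulator, agonist, inhibitor
negative modulator, antagonist
negative modulator, binder, inhibitor
negative modulator, inhibitor
partial antagonist
suppressor
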