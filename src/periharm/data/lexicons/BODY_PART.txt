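wrist
hand
torso
arm
leg
thigh
neck
head
skin
forearm
stomach
abdomen
face
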