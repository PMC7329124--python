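no	ABSENT	no	forward
not	ABSENT	not	forward
no evidence of	ABSENT	no\s+(definite\s+)?evidence\s+(of|for)	forward
without	ABSENT	without(\s+evidence\s+of)?	forward
negative for	ABSENT	negative\s+for	forward
absence of	ABSENT	absence\s+of	forward
is not seen	ABSENT	(is|are)\s+not\s+(seen|identified|visualized|appreciated)	backward
is excluded	ABSENT	(is|are|was|were)\s+excluded	backward
evidence of	PRESENT	evidence\s+(of|for)	forward
consistent with	PRESENT	(consistent|compatible)\s+with	forward
multifocal	PRESENT	multifocal	forward
in the	PRESENT	in\s+the	bidirectional
is present	PRESENT	(is|are)\s+(present|identified|seen|noted|visualized|demonstrated|redemonstrated)	backward
demonstrates	PRESENT	demonstrat(es|ing)	forward
possible	SUSPECTED	possible|probable|likely	forward
suspected	SUSPECTED	suspected|suspicious\s+for|concerning\s+for|worrisome\s+for	forward
may represent	SUSPECTED	may\s+(represent|reflect|indicate)	forward
may be present	SUSPECTED	may\s+be\s+present	backward
is suspected	SUSPECTED	(is|are)\s+suspected	backward
was not excluded	INDETERMINATE	(was|were)\snot\sexcluded	backward
cannot be excluded	INDETERMINATE	cannot\s+be\s+(excluded|ruled\s+out)|could\s+not\s+be\s+(excluded|ruled\s+out)	backward
cannot exclude	INDETERMINATE	cannot\s+(exclude|rule\s+out)	forward
versus	INDETERMINATE	versus	bidirectional
do not appear significantly changed	INDETERMINATE	do(es)?\s+not\s+appear\s+(significantly\s+)?changed	backward
is normal	NORMAL	(is|are)\s+normal	backward
is unremarkable	NORMAL	(is|are)\s+unremarkable	backward
is preserved	NORMAL	(is|are)\s+(preserved|maintained|patent|intact)	backward
is within normal limits	NORMAL	(is|are)\s+within\s+normal\s+limits	backward
appears normal	NORMAL	appears?\s+normal	backward
normal	NORMAL	normal	forward
is abnormal	ABNORMAL	(is|are)\s+abnormal	backward
is effaced	ABNORMAL	(is|are)\s+effaced	backward
loss of	ABNORMAL	loss\s+of	forward
effacement of	ABNORMAL	effacement\s+of	forward
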