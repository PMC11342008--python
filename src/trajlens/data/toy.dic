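%
1	ppron
2	i
3	we
4	you
5	shehe
6	they
7	affect
8	posemo
9	negemo
10	anger
11	sad
12	anx
13	social
14	cogproc
15	insight
16	cause
17	percept
18	see
19	hear
20	feel
21	bio
22	body
23	health
24	drives
25	achieve
26	power
27	relativ
28	motion
29	space
30	time
31	focuspast
32	focuspresent
33	focusfuture
34	pconcern
35	work
36	death
%
i	2
me	2
my	2
mine	2
myself	2
we	3
us	3
our	3
ours	3
you	4
your	4
yours	4
she	5
he	5
her	5
him	5
his	5
they	6
them	6
their	6
happy	8
good	8
love	8 13
nice	8
glad	8
great	8
hope*	8 33
joy*	8
hate*	10
angr*	10
mad	10
rage*	10
annoy*	10
fight*	10
kill*	10 36
sad*	11
cry*	11
grief*	11
hopeless*	11
miser*	11
lonel*	11 13
worr*	12
fear*	12
afraid	12
nervous*	12
anxi*	12
talk*	13
friend*	13
family	13
mother	13
father	13
people	13
everyone	13
share*	13
think*	15
know*	15
realiz*	15
understand*	15
aware*	15
because	16
why	16
reason*	16
effect*	16
therefore	16
see	18
saw	18
look*	18
watch*	18
hear*	19
listen*	19
sound*	19
feel*	20
touch*	20
numb*	20
head	22
heart*	22
hand*	22
sleep*	22
blood	22
brain	22
sick*	23
pain*	23
doctor*	23
ill	23
hospital*	23
medic*	23
therap*	23
win*	25
succe*	25
fail*	25
goal*	25
achiev*	25
try*	25
effort*	25
control*	26
power*	26
weak*	26
strong*	26
go	28
going	28
went	28
walk*	28
move*	28
run*	28
drive*	28
travel*	28
in	29
out	29
up	29
down	29
here	29
there	29
place*	29
room*	29
today	30 32
soon	30 33
late*	30
hour*	30
day*	30
time	30
week*	30
year*	30
was	31
were	31
did	31
had	31
ago	31
yesterday	31
is	32
am	32
are	32
now	32
currently	32
will	33
gonna	33
future*	33
tomorrow	33
plan*	33
job*	35
school*	35
work*	35
boss*	35
career*	35
death*	36
die*	36
dead*	36
dying	36
suicid*	36
grave*	36
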