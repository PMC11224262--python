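# word	polarity	subjectivity
abhorrent	-0.9	0.9
absolutely	0	0.8
abysmal	-0.9	0.9
acceptable	0.3	0.5
actually	0	0.8
adequate	0.3	0.5
admirable	0.7	0.7
adorable	0.8	0.8
affordable	0.3	0.5
afraid	-0.5	0.6
aggressive	-0.6	0.7
agonizing	-0.7	0.7
agreeable	0.3	0.5
alarming	-0.7	0.7
amazing	0.9	0.9
angry	-0.5	0.6
annoying	-0.3	0.5
annual	0.1	0.2
anxious	-0.4	0.5
appalling	-0.8	0.8
apparently	0	0.8
arguably	0	0.8
arrogant	-0.6	0.7
ashamed	-0.5	0.6
assume	0	0.6
atrocious	-0.8	0.8
available	0.1	0.2
awesome	0.9	0.9
awful	-0.6	0.7
awkward	-0.2	0.4
bad	-0.4	0.5
balanced	0.2	0.4
basically	0	0.8
beautiful	0.8	0.8
believe	0	0.6
believed	0	0.6
beneficial	0.5	0.6
betrayed	-0.5	0.6
better	0.4	0.5
bitter	-0.5	0.6
bland	-0.2	0.4
blissful	0.8	0.8
boring	-0.2	0.4
breathtaking	0.9	0.9
brief	-0.1	0.2
bright	0.3	0.5
brilliant	0.9	0.9
calm	0.4	0.5
capable	0.5	0.6
careless	-0.3	0.5
caring	0.6	0.7
catastrophic	-0.8	0.8
central	0.1	0.2
certainly	0	0.8
charming	0.8	0.8
cheerful	0.7	0.7
clean	0.3	0.5
clear	0.3	0.5
closed	-0.1	0.2
clumsy	-0.3	0.5
coherent	0.2	0.4
comfortable	0.4	0.5
comforting	0.6	0.7
common	0.1	0.2
compassionate	0.6	0.7
confident	0.5	0.6
confusing	-0.2	0.4
considerate	0.6	0.7
consistent	0.2	0.4
contemptible	-0.8	0.8
content	0.4	0.5
convenient	0.3	0.5
crowded	-0.3	0.5
cruel	-0.6	0.7
curious	0.2	0.4
daily	0.1	0.2
damaging	-0.7	0.7
dangerous	-0.7	0.7
deceitful	-0.6	0.7
decent	0.4	0.5
definitely	0	0.8
delayed	-0.1	0.2
delighted	0.7	0.7
delightful	0.9	0.9
dependable	0.4	0.5
depressing	-0.7	0.7
despicable	-0.8	0.8
destructive	-0.7	0.7
devastating	-0.8	0.8
dirty	-0.6	0.7
disappointing	-0.3	0.5
discouraged	-0.4	0.5
disgusting	-0.8	0.8
dishonest	-0.6	0.7
distant	-0.1	0.2
distressing	-0.7	0.7
doubtful	-0.2	0.4
draining	-0.7	0.7
dreadful	-0.7	0.7
dull	-0.2	0.4
early	0.1	0.2
easy	0.3	0.5
ecstatic	0.8	0.8
effective	0.5	0.6
efficient	0.2	0.4
elated	0.8	0.8
embarrassed	-0.5	0.6
encouraging	0.6	0.7
energetic	0.5	0.6
enjoyable	0.6	0.7
enthusiastic	0.5	0.6
envious	-0.5	0.6
essentially	0	0.8
euphoric	0.8	0.8
evil	-0.9	0.9
excellent	0.8	0.8
excruciating	-0.9	0.9
exhausting	-0.7	0.7
exhilarating	0.8	0.8
expect	0	0.6
exquisite	0.9	0.9
fair	0.4	0.5
fantastic	0.9	0.9
faulty	-0.3	0.5
favorable	0.5	0.6
fearful	-0.5	0.6
feasible	0.2	0.4
feel	0	0.6
feeling	0	0.6
felt	0	0.6
final	-0.1	0.2
fine	0.3	0.5
first	0.1	0.2
flawed	-0.3	0.5
flawless	0.9	0.9
flexible	0.2	0.4
forgettable	-0.2	0.4
fortunate	0.5	0.6
foul	-0.6	0.7
frankly	0	0.8
frequent	0.1	0.2
fresh	0.3	0.5
friendly	0.6	0.7
frightening	-0.7	0.7
frustrating	-0.3	0.5
generous	0.7	0.7
gentle	0.6	0.7
genuine	0.4	0.5
glad	0.7	0.7
gloomy	-0.4	0.5
glorious	0.9	0.9
good	0.7	0.7
gorgeous	0.8	0.8
graceful	0.7	0.7
grateful	0.7	0.7
great	0.8	0.8
greedy	-0.6	0.7
gross	-0.6	0.7
guess	0	0.6
guilty	-0.4	0.5
handy	0.2	0.4
happy	0.7	0.7
harmful	-0.7	0.7
harsh	-0.6	0.7
hateful	-0.8	0.8
healthy	0.5	0.6
heartwarming	0.7	0.7
heavenly	0.9	0.9
heinous	-0.9	0.9
helpful	0.5	0.6
helpless	-0.5	0.6
hesitant	-0.2	0.4
honest	0.4	0.5
honestly	0	0.8
hope	0	0.6
hopeful	0.7	0.7
hopeless	-0.5	0.6
hopelessly	-0.9	0.9
horrendous	-0.8	0.8
horrible	-0.7	0.7
horrific	-0.8	0.8
horrifying	-0.9	0.9
hostile	-0.6	0.7
humiliated	-0.5	0.6
hurt	-0.5	0.6
ignored	-0.5	0.6
imagine	0	0.6
impressive	0.7	0.7
improved	0.4	0.5
improving	0.4	0.5
inconvenient	-0.3	0.5
incredible	0.9	0.9
inspiring	0.7	0.7
interesting	0.2	0.4
irregular	-0.1	0.2
irritating	-0.3	0.5
isolated	-0.4	0.5
jealous	-0.5	0.6
joyful	0.8	0.8
kind	0.6	0.7
kindhearted	0.7	0.7
lacking	-0.3	0.5
last	-0.1	0.2
late	-0.1	0.2
limited	-0.1	0.2
literally	0	0.8
lively	0.5	0.6
loathsome	-0.8	0.8
local	0.1	0.2
lonely	-0.4	0.5
lovely	0.8	0.8
loving	0.6	0.7
lucky	0.5	0.6
mad	-0.5	0.6
magnificent	0.9	0.9
main	0.1	0.2
marvelous	0.9	0.9
maybe	0	0.8
mean	-0.6	0.7
mediocre	-0.2	0.4
messy	-0.3	0.5
mild	0.2	0.4
minor	-0.1	0.2
miserable	-0.7	0.7
missing	-0.1	0.2
moderate	0.2	0.4
modern	0.2	0.4
monstrous	-0.9	0.9
moody	-0.4	0.5
nasty	-0.6	0.7
national	0.1	0.2
need	0	0.6
neglected	-0.5	0.6
nervous	-0.4	0.5
new	0.1	0.2
nice	0.6	0.7
nightmarish	-0.8	0.8
noisy	-0.3	0.5
normal	0.1	0.2
notable	0.2	0.4
novel	0.2	0.4
occasional	-0.1	0.2
odd	-0.2	0.4
okay	0.3	0.5
old	-0.1	0.2
open	0.1	0.2
optimistic	0.7	0.7
organized	0.2	0.4
outstanding	0.9	0.9
overjoyed	0.8	0.8
painful	-0.7	0.7
partial	-0.1	0.2
peaceful	0.4	0.5
perfect	0.9	0.9
perhaps	0	0.8
personally	0	0.8
pessimistic	-0.4	0.5
phenomenal	0.9	0.9
plain	-0.2	0.4
plausible	0.2	0.4
pleasant	0.6	0.7
pleased	0.7	0.7
poor	-0.4	0.5
positive	0.5	0.6
possibly	0	0.8
practical	0.2	0.4
praiseworthy	0.7	0.7
prefer	0	0.6
presumably	0	0.8
private	-0.1	0.2
probably	0	0.8
productive	0.5	0.6
promising	0.5	0.6
public	0.1	0.2
radiant	0.8	0.8
rare	-0.1	0.2
reasonable	0.4	0.5
recent	0.1	0.2
reduced	-0.1	0.2
refreshing	0.6	0.7
regretful	-0.4	0.5
regular	0.1	0.2
rejected	-0.5	0.6
relaxed	0.4	0.5
reliable	0.4	0.5
remarkable	0.7	0.7
remember	0	0.6
remote	-0.1	0.2
repulsive	-0.8	0.8
resentful	-0.5	0.6
restless	-0.4	0.5
revolting	-0.8	0.8
rewarding	0.6	0.7
rotten	-0.6	0.7
rude	-0.6	0.7
ruinous	-0.8	0.8
sad	-0.4	0.5
safe	0.3	0.5
satisfactory	0.3	0.5
satisfying	0.6	0.7
scary	-0.7	0.7
secure	0.3	0.5
seemingly	0	0.8
selfish	-0.6	0.7
sensible	0.4	0.5
shaky	-0.3	0.5
short	-0.1	0.2
sickening	-0.8	0.8
simple	0.2	0.4
sincere	0.4	0.5
sloppy	-0.3	0.5
slow	-0.2	0.4
small	-0.1	0.2
smooth	0.3	0.5
solid	0.4	0.5
soothing	0.6	0.7
sorry	-0.4	0.5
soulcrushing	-0.9	0.9
spectacular	0.9	0.9
splendid	0.8	0.8
stable	0.3	0.5
standard	0.1	0.2
steady	0.3	0.5
straightforward	0.2	0.4
strange	-0.2	0.4
stressed	-0.4	0.5
strong	0.5	0.6
stunning	0.8	0.8
sublime	0.9	0.9
successful	0.5	0.6
superb	0.9	0.9
supportive	0.6	0.7
suppose	0	0.6
supposedly	0	0.8
surely	0	0.8
suspect	0	0.6
tedious	-0.2	0.4
tense	-0.4	0.5
terrible	-0.7	0.7
terrific	0.8	0.8
terrifying	-0.9	0.9
thankful	0.7	0.7
think	0	0.6
thought	0	0.6
thoughtful	0.6	0.7
threatening	-0.7	0.7
thrilled	0.8	0.8
tidy	0.3	0.5
tiresome	-0.3	0.5
tolerable	0.3	0.5
torturous	-0.9	0.9
toxic	-0.7	0.7
tragic	-0.8	0.8
traumatic	-0.8	0.8
trustworthy	0.4	0.5
typical	0.1	0.2
ugly	-0.6	0.7
unbearable	-0.7	0.7
unbearably	-0.9	0.9
uncertain	-0.2	0.4
unclear	-0.2	0.4
uncomfortable	-0.3	0.5
uneasy	-0.2	0.4
unfair	-0.6	0.7
unforgivable	-0.9	0.9
unhappy	-0.4	0.5
unjust	-0.6	0.7
unpleasant	-0.3	0.5
unreliable	-0.3	0.5
unsatisfying	-0.3	0.5
unsure	-0.2	0.4
unusual	-0.2	0.4
uplifting	0.8	0.8
upset	-0.5	0.6
useful	0.5	0.6
usual	0.1	0.2
vague	-0.2	0.4
valuable	0.5	0.6
vibrant	0.5	0.6
vile	-0.8	0.8
want	0	0.6
warm	0.6	0.7
warmhearted	0.7	0.7
weak	-0.4	0.5
welcoming	0.6	0.7
wish	0	0.6
wonder	0	0.6
wonderful	0.9	0.9
worried	-0.4	0.5
worthless	-0.9	0.9
worthwhile	0.4	0.5
worthy	0.2	0.4
wounded	-0.5	0.6
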